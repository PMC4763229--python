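# Methods

## Generative model for flow events

An event on reporter channel *r* is

    true_ir = U_i · a_r · t_m(r) · ε_ir + b_r,      observed_i = true_i · Sᵀ

- **Uptake** `U_i ~ 10^N(μ_U, σ_U)`, shared by all co-delivered mRNAs in a
  cell. Defaults `μ_U = 3.0` (median 10³ a.u.), `σ_U = 0.5` decades — a
  broad, decade-spanning spread, reflecting that transfected-cell brightness
  varies mainly through how much mRNA each cell takes up. A configurable
  fraction of events is untransfected (`U_i = 0`, background only); the
  default is 0, and pipelines that set it nonzero should gate on the
  denominator channel (default gate: > 10 × background).
- **Translational efficiency** `t` is the fraction of translation retained
  under the channel's target miRNA in the event's cell type (1 for
  controls). Cell types may declare weighted subpopulations with their own
  knockdown maps to model intra-line heterogeneity.
- **Ratio noise** `ε_ir ~ 10^N(0, σ/√2)`, independent per channel given
  `U_i`. The parameter `ratio_noise_log10_sd` (σ) is deliberately the log10
  SD of a **two-channel ratio**, so two independent channel draws compose to
  exactly σ; the central-95% fold-width of a control/control ratio is then
  the closed form `10^(2·1.96·σ)`.
- **Background** `b_r` is additive per channel, **spillover** is the
  standard linear cytometry mixing model (`observed = true · Sᵀ`, unit
  diagonal, inverted exactly by compensation).

Defaults are chosen once as study conditions. σ = 0.10 (95% width
`10^(0.392)` ≈ 2.5-fold) sits in the window derived from the two behaviours
the ratiometric strategy rests on: a single ~1.5-fold activity shift must
*not* split a 1:1 mixture (requires σ > log10(1.5)/2 ≈ 0.088), while the
compound ~1.95-fold shift of a dual sensor with 1.3-/1.5-fold opposing
differences must split it robustly, i.e. with a KDE dip prominence well
above the 0.1 × max detection threshold (requires σ ≲ 0.105 after Silverman
smoothing at n = 10⁴). Both widths remain comfortably "within four-fold".
Background defaults to 0 so that the default model is the pure ratio model
with analytically known centers; nonzero background (and the associated
gate) is a first-class option, not the default, because an additive offset
biases log-ratio centers by O(b/U) and would contaminate closed-form
parameter-recovery checks.

## Quantification

- **Compensation** solves `observed = true · Sᵀ` per event; entries driven
  negative are clipped to 0 and counted.
- **Translational efficiency** is a ratio of arithmetic means —
  `[mean(rep)/mean(ref)]` in the reporter sample divided by the same in the
  no-target control sample — not a mean of per-event ratios; per-event
  ratios are used only for histograms and classification. Standard errors
  come from a seeded bootstrap over events (200 resamples by default);
  fold-changes between efficiencies propagate SEs by the delta method on
  the log scale.
- **Peak width** is the package's convention for the fold-range of a ratio
  peak: the ratio of the upper to the lower quantile bracketing the central
  95% (configurable coverage) of events. It is scale-invariant and
  monotone in coverage.
- **Mode counting** evaluates a Gaussian KDE (Silverman bandwidth) on the
  log10 ratios over a 512-point grid; a mode is a local maximum whose
  height *and* topographic prominence both exceed 0.1 × the global maximum.
  The height condition alone cannot reject sampling wobble on the flat top
  of a merged peak (every wobble near the maximum trivially clears a height
  threshold), so the prominence condition carries the real discrimination.
  Zero-variance input counts as one mode by convention; at least 50 events
  are required.

## Panel design

With denominator sensor x, cell type A sits at coordinates
`log10(T_A(s_j)/T_A(x))` per non-denominator sensor `s_j`; the distance
between two cell types is Euclidean in that log10 space, and a panel's
score is the minimum over all cell-type pairs. The exhaustive search
enumerates every denominator × every unordered choice of remaining sensors
(`m·C(m−1, k−1)` candidates; axis permutations are score-equivalent and
deduplicated), ranks by score, and breaks ties lexicographically. Euclidean
distance in log-ratio space is the package's reading of "distance made by a
set of sensors": it is the unique choice consistent with plotting cells on
decade-scaled ratio axes and extending from 2-D to 3-D "in a similar
manner". Distances are invariant to rescaling any cell type's whole
efficiency column (absolute uptake is uninformative) — this is enforced by
property tests.

The design/measurement round trip closes numerically: centroids predicted
from an efficiency table agree with geometric-mean log-ratios measured on
simulated events from the same profiles within Monte-Carlo error.

## Classification and capacity

Events (or nuclei) are assigned to the nearest predicted centroid
(Euclidean in log10 ratio space, ties to the first-listed class) — the
primary classifier, because cluster identity is established by *predicted*
positions rather than unsupervised structure. Rectangular gates with
half-open `[low, high)` bounds per axis provide the imaging-style
alternative; gates must be pairwise disjoint and events in no gate are
UNASSIGNED. Reported accuracy is over assigned events, with the unassigned
fraction tracked separately; recall counts unassigned as misses.

Capacity uses an equality-allowed packing rule: an axis spanning a D-fold
dynamic range holds `floor(log D / log W) + 1` peak centers spaced at least
a W-fold peak width apart, and independent axes multiply. With the
measured ~2.5-fold default width, a 16-fold dilution range yields 3 slots
per axis — dozens of types in 2-D, low hundreds in 3-D — which is the
package's quantitative rendering of an otherwise qualitative claim.

## Imaging cytometry

Scenes are simulated as non-overlapping disks (nuclear-localised reporters)
over constant background, each disk drawing a cell type, uptake and channel
noise exactly as a flow event, plus per-pixel multiplicative noise (default
0.05 log10 units). Segmentation: Otsu's threshold on `log10(average + 1)` of
the channel-average image — the log transform keeps dim nuclei above
threshold despite the decade-wide brightness spread — then 8-connected
components, dropping components under 20 px (noise specks). Per nucleus, the
geometric mean of per-pixel ratios is computed as the exponentiated mean of
log10 ratios over pixels with strictly positive channels (numerically
stable, and algebraically equal to the ratio of per-pixel geometric means).
Pseudo-colouring maps `log10 R` linearly onto [0, 1] over a per-ratio
display window (e.g. −0.25…0.75 decades), clipping outside. Watershed
splitting and illumination correction are deliberately out of scope: the
generator guarantees separated nuclei and flat illumination, so passing
imaging tests says nothing about clumped nuclei or shading in real
micrographs.

## What the simulator does and does not emulate

Emulated: shared log-normal uptake, per-sensor multiplicative knockdown,
tight ratio noise, linear spillover, cell-type mixtures and intra-type
subpopulations, untransfected events, nuclear-disk imaging with pixel
noise. Not emulated: mRNA degradation kinetics and delivery chemistry,
scatter-based viability gating, instrument saturation, autofluorescence
spectra beyond a flat additive term, nucleus shape irregularity and
overlap. Tests passing on this generator therefore validate the *analysis
logic* (compensation algebra, ratio statistics, design geometry,
classification), not the biology of any particular cell line; the shipped
HeLa/293FT/MCF-7 efficiency table is a synthetic stand-in that reproduces
the reported fold-relations (1.3-/1.5-fold opposing differences, all under
two-fold), not measured data.

## Numerical choices and degenerate inputs

- All randomness flows from one integer seed per simulation
  (`numpy.random.default_rng`); identical config ⇒ byte-identical outputs.
- Compensation requires an invertible spillover matrix (checked, with the
  matrix named in the failure); determinant tolerance 1e−12.
- Ratios require strictly positive channels; excluded events are counted,
  never silently dropped from totals.
- `peak_width` refuses < 20 events; `count_modes` refuses < 50.
- Scene generation uses rejection sampling with a bounded attempt budget
  and fails loudly when the requested nuclei cannot fit.
- Problem sizes in the shipped scenarios (10⁴ events for peak statistics,
  9 × 10³ for three-type clustering, ≤ 360² px scenes with ≤ 60 nuclei)
  give Monte-Carlo errors comfortably below the effect sizes under study
  while keeping any single analysis under a few seconds.
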