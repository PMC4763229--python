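# hric — high-resolution identification of cell types from miRNA-sensor ratios

`hric` is a Python package for designing and analysing ratiometric
miRNA-sensor experiments: live cells are transfected with a small set of
in-vitro-transcribed reporter mRNAs, each carrying a fully complementary
target site for one miRNA in its 5′ UTR, and each encoding a different
fluorescent protein. Because co-delivered mRNAs share each cell's uptake,
the **ratio** of two reporter intensities is nearly constant across cells —
its peak spans well under four-fold — while a miRNA target site rescales
that ratio by the miRNA's activity in the cell at hand. Pointing two sensors
at miRNAs with *opposing* activity differences compounds the shifts: two
sub-two-fold activity differences become a ~four-fold ratio separation,
enough to split otherwise indistinguishable cell types into clean peaks.

The package is aimed at computational biologists and synthetic-biology
groups who want to (a) simulate such experiments with full ground truth,
(b) choose which miRNAs to target, and (c) classify flow-cytometry events or
imaged nuclei by cell type.

## The model

Per event *i* and reporter channel *r*:

```
true_ir = U_i · a_r · t_m(r) · ε_ir + b_r        observed = true · Sᵀ
```

where `U_i` is the shared per-cell mRNA uptake (log10-normal), `a_r` a
brightness/dose factor, `t_m` the **translational efficiency** of the
channel's target miRNA in the event's cell type (t = 1 for a no-target
control; lower t = more active miRNA), `ε_ir` tight multiplicative noise,
`b_r` autofluorescence background, and `S` a linear spectral spillover
matrix. Dividing two channels cancels `U_i`, so log-ratios cluster tightly
around `log10(a_num t_num / a_den t_den)`.

Panel design works entirely on a `T[miRNA, cell type]` efficiency table: a
panel (x, y, z) with x on the denominator channel places cell type A at
`(log10 T_A(y)/T_A(x), log10 T_A(z)/T_A(x))`; panels are scored by the
**minimum pairwise Euclidean distance** between cell-type centroids in that
log-ratio space, and the exhaustive ranking maximises the worst-separated
pair.

## Worked example

```python
from hric import enumerate_sets, synthetic_efficiency_table
from hric.scenarios import control_peak_width, mixture_mode_counts

table = synthetic_efficiency_table()           # synthetic HeLa/293FT/MCF-7 table
report = enumerate_sets(table, k=3, top_n=3)
print(report.table[["denominator", "sensor_1", "sensor_2", "d_min"]].round(3))
print(control_peak_width(seed=1))
print(mixture_mode_counts(seed=1))
```

prints

```
  denominator    sensor_1   sensor_2  d_min
0   miR-17-5p  miR-127-3p   miR-203a  0.329
1   miR-24-3p  miR-127-3p   miR-203a  0.310
2  miR-127-3p   miR-17-5p  miR-24-3p  0.298
{'peak_width_fold': 2.460..., 'n': 10000}
{'dual_sensor_modes': 2, 'single_sensor_modes_miR203a': 1,
 'single_sensor_modes_miR24': 1, 'n': 10000}
```

Reading this: the best three-sensor panel puts its denominator sensor on
miR-17-5p and guarantees every pair of the three cell types is at least
10^0.329 ≈ 2.1-fold apart along some combination of ratio axes. A
co-transfected control pair's 95% ratio peak spans 2.4-fold (within the
four-fold envelope, closed form 10^(2·1.96·0.10) ≈ 2.5), and on a 1:1
HeLa/MCF-7 mixture the dual sensor
(miR-24-3p on the denominator, miR-203a on the numerator — 1.3-fold and
1.5-fold opposing activity differences) splits the ratio histogram into two
modes while either sensor alone leaves one.

The same stages are scriptable from the shell (`hric simulate-flow`,
`hric analyze`, `hric design rank`, `hric simulate-images`, `hric imaging`),
each taking `--config config.yaml --seed N --out DIR` and writing a
`manifest.json` alongside CSV/JSON/PNG/TIFF artifacts.

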