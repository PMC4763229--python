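"""Domain objects for miRNA-sensor cytometry.

A *miRNA-responsive mRNA* (sensor) is an in-vitro-transcribed reporter mRNA
carrying a fully complementary target site for one miRNA in its 5' UTR.  In a
cell where that miRNA is active, translation of the reporter is repressed by a
multiplicative factor -- the *translational efficiency* ``t`` (t = 1 means no
repression, i.e. the sensor behaves like a no-target control).  A cell type is
therefore characterised, for our purposes, by its vector of translational
efficiencies over the sensors in play.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Sentinel target meaning "no miRNA target site" (control mRNA).
CONTROL = "CONTROL"


@dataclass(frozen=True)
class Subpopulation:
    """One component of an intra-type mixture (e.g. a HeLa subgroup)."""

    weight: float
    knockdown: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"subpopulation weight must be > 0, got {self.weight}")
        _check_knockdown(self.knockdown)


def _check_knockdown(knockdown: Mapping[str, float]) -> None:
    for mirna, t in knockdown.items():
        if not t > 0:
            raise ValueError(
                f"translational efficiency for {mirna!r} must be > 0, got {t}"
            )


@dataclass
class CellTypeProfile:
    """A cell type's miRNA-activity signature.

    Parameters
    ----------
    name : str
        Label used for ground truth and reports.
    knockdown : mapping
        miRNA identifier -> translational efficiency ``t`` (dimensionless,
        multiplicative translation retained under that miRNA; ``t = 1``
        means the miRNA is inactive).
    subpopulations : sequence of Subpopulation, optional
        Intra-type heterogeneity: each component carries its own knockdown
        map (entries override the top-level map) and a mixing weight.
        Weights must sum to 1.
    """

    name: str
    knockdown: Mapping[str, float]
    subpopulations: Sequence[Subpopulation] | None = None

    def __post_init__(self) -> None:
        _check_knockdown(self.knockdown)
        if self.subpopulations is not None:
            if not self.subpopulations:
                raise ValueError("subpopulations, when given, must be non-empty")
            total = sum(s.weight for s in self.subpopulations)
            if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"subpopulation weights must sum to 1, got {total}"
                )

    def efficiency(self, target: str, subpopulation: int | None = None) -> float:
        """Translational efficiency of a sensor targeting ``target``.

        CONTROL sensors always return 1.  Unknown targets raise ``KeyError``.
        """
        if target == CONTROL:
            return 1.0
        if subpopulation is not None:
            if self.subpopulations is None:
                raise ValueError(f"profile {self.name!r} has no subpopulations")
            sub = self.subpopulations[subpopulation]
            if target in sub.knockdown:
                return float(sub.knockdown[target])
        if target not in self.knockdown:
            raise KeyError(
                f"miRNA {target!r} is not in the knockdown map of cell type "
                f"{self.name!r} (known: {sorted(self.knockdown)})"
            )
        return float(self.knockdown[target])

    @property
    def n_subpopulations(self) -> int:
        return 0 if self.subpopulations is None else len(self.subpopulations)


@dataclass(frozen=True)
class Sensor:
    """One reporter channel: a fluorescent protein plus its miRNA target."""

    channel: str
    target: str = CONTROL
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if not self.brightness > 0:
            raise ValueError(f"brightness must be > 0, got {self.brightness}")


@dataclass
class SensorSet:
    """Ordered assignment of miRNA targets to reporter channels.

    One channel is the ratio denominator: every fluorescence ratio in the
    analysis divides the other channels by it, cancelling the per-cell mRNA
    uptake.
    """

    sensors: Sequence[Sensor]
    denominator: str

    def __post_init__(self) -> None:
        names = [s.channel for s in self.sensors]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")
        if not 2 <= len(names) <= 4:
            raise ValueError(f"need 2-4 channels, got {len(names)}")
        if self.denominator not in names:
            raise ValueError(
                f"denominator {self.denominator!r} is not a channel (channels: {names})"
            )

    @property
    def channels(self) -> list[str]:
        return [s.channel for s in self.sensors]

    @property
    def numerators(self) -> list[str]:
        return [s.channel for s in self.sensors if s.channel != self.denominator]

    @property
    def k(self) -> int:
        return len(self.sensors)

    @property
    def brightness(self) -> np.ndarray:
        return np.array([s.brightness for s in self.sensors], dtype=float)

    def sensor(self, channel: str) -> Sensor:
        for s in self.sensors:
            if s.channel == channel:
                return s
        raise KeyError(channel)

    def targets(self) -> list[str]:
        return [s.target for s in self.sensors]

    def with_brightness(self, channel: str, factor: float) -> "SensorSet":
        """Return a copy with one channel's brightness multiplied by ``factor``."""
        new = [
            Sensor(s.channel, s.target, s.brightness * factor)
            if s.channel == channel
            else s
            for s in self.sensors
        ]
        return SensorSet(new, self.denominator)


@dataclass
class SpilloverMatrix:
    """Linear spectral mixing matrix S.

    ``S[i, j]`` is the fraction of fluorophore ``i``'s signal detected in
    channel ``j``; the diagonal is 1.  Observed events are ``true @ S.T``;
    compensation inverts that product.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError(f"spillover matrix must be square, got shape {S.shape}")
        if not np.allclose(np.diag(S), 1.0):
            raise ValueError("spillover matrix must have unit diagonal")
        if (S < 0).any():
            raise ValueError("spillover fractions must be non-negative")
        if abs(np.linalg.det(S)) < 1e-12:
            raise ValueError("spillover matrix is singular and cannot be compensated")
        self.matrix = S

    @classmethod
    def identity(cls, k: int) -> "SpilloverMatrix":
        return cls(np.eye(k))

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SimulationConfig:
    """Parameters of the generative flow-cytometry model.

    The per-event model for channel ``r`` is::

        true_r = U_i * a_r * t_{m(r)} * eps_ir + background_r

    with ``U_i`` the per-cell mRNA uptake, shared across co-delivered mRNAs
    and log10-normal with (``uptake_log10_mean``, ``uptake_log10_sd``);
    ``a_r`` the channel brightness/dose factor; ``t`` the translational
    efficiency of the targeted miRNA in the event's cell type; and ``eps``
    tight multiplicative noise.  ``ratio_noise_log10_sd`` is the log10
    standard deviation of the *ratio of any two channels*: each channel's
    ``eps`` is drawn with sd ``ratio_noise_log10_sd / sqrt(2)`` so that two
    independent channel noises compose to exactly that ratio spread.  The
    default 0.10 puts the central-95% fold-width of a control/control ratio
    at 10^(2*1.96*0.10) ~ 2.5-fold, inside the ~4-fold envelope observed for
    co-transfected reporters and tight enough that a ~2-fold compound ratio
    shift separates two cell types into distinct modes.
    """

    n_events: int = 10_000
    uptake_log10_mean: float = 3.0
    uptake_log10_sd: float = 0.5
    ratio_noise_log10_sd: float = 0.10
    background: float | Sequence[float] = 0.0
    untransfected_fraction: float = 0.0
    spillover: SpilloverMatrix | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if self.uptake_log10_sd < 0 or self.ratio_noise_log10_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.untransfected_fraction <= 1:
            raise ValueError("untransfected_fraction must be in [0, 1]")
        if np.any(np.asarray(self.background, dtype=float) < 0):
            raise ValueError("background must be >= 0")

    def background_vector(self, k: int) -> np.ndarray:
        b = np.asarray(self.background, dtype=float)
        if b.ndim == 0:
            return np.full(k, float(b))
        if b.shape != (k,):
            raise ValueError(f"background has length {b.shape}, expected {k}")
        return b

    def channel_noise_sd(self) -> float:
        """Per-channel log10 sd of eps (ratio sd / sqrt(2))."""
        return self.ratio_noise_log10_sd / math.sqrt(2.0)
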