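"""Classification of events in log-ratio space, separation quality metrics,
and the packing-based capacity estimate.

Two classifiers are provided: nearest-centroid against positions predicted
from an efficiency table (or learned from labelled events), and rectangular
gates in log10 ratio units.  Both operate on (n_events, n_axes) arrays of
log10 ratio coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .ratiometrics import RatioTable

#: Label for events falling in no gate.
UNASSIGNED = "UNASSIGNED"


def _coords(ratios) -> np.ndarray:
    if isinstance(ratios, RatioTable):
        return ratios.log10()
    return np.asarray(ratios, dtype=float)


# ---------------------------------------------------------------------------
# nearest centroid


class NearestCentroidRatioClassifier(ClassifierMixin, BaseEstimator):
    """Assign events to the nearest predicted cell-type centroid.

    Centroids live in (k-1)-dimensional log10 fluorescence-ratio space and
    can either be supplied directly (typically from the design engine's
    predictions) or learned as per-class means of labelled log-ratio
    coordinates.  Ties go to the first-listed centroid.

    Parameters
    ----------
    centroids : mapping label -> coordinate array, optional
        Fixed centroids; when given, ``fit`` only records them (``X`` may be
        None) and insertion order defines the tie-break order.
    """

    def __init__(self, centroids: Mapping[str, Sequence[float]] | None = None):
        self.centroids = centroids

    def fit(self, X=None, y=None):
        if self.centroids is not None:
            if len(self.centroids) == 0:
                raise ValueError("centroid list is empty")
            self.classes_ = np.array(list(self.centroids), dtype=object)
            self.centroids_ = np.array(
                [np.asarray(v, dtype=float) for v in self.centroids.values()]
            )
        else:
            if X is None or y is None:
                raise ValueError("without fixed centroids, fit needs X and y")
            X = check_array(X)
            y = np.asarray(y)
            self.classes_ = np.unique(y)
            self.centroids_ = np.array(
                [X[y == c].mean(axis=0) for c in self.classes_]
            )
        self.n_features_in_ = self.centroids_.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "centroids_")
        X = check_array(X)
        if X.shape[1] != self.centroids_.shape[1]:
            raise ValueError(
                f"events have {X.shape[1]} axes, centroids have "
                f"{self.centroids_.shape[1]}"
            )
        d2 = ((X[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]


def classify_nearest_centroid(
    ratios: RatioTable | np.ndarray, centroids: Mapping[str, Sequence[float]]
) -> np.ndarray:
    """Nearest-centroid labels for log10 ratio coordinates (RatioTable ok)."""
    clf = NearestCentroidRatioClassifier(centroids).fit()
    return clf.predict(_coords(ratios))


# ---------------------------------------------------------------------------
# gates


@dataclass
class GateBox:
    """Axis-aligned box in log10 ratio units with half-open bounds.

    An event belongs to the gate iff ``low <= v < high`` on every axis.
    """

    label: str
    bounds: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        self.bounds = [(float(lo), float(hi)) for lo, hi in self.bounds]
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(
                    f"gate {self.label!r}: low must be < high, got ({lo}, {hi})"
                )

    @property
    def n_axes(self) -> int:
        return len(self.bounds)

    def contains(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        inside = np.ones(X.shape[0], dtype=bool)
        for axis, (lo, hi) in enumerate(self.bounds):
            inside &= (X[:, axis] >= lo) & (X[:, axis] < hi)
        return inside

    def overlaps(self, other: "GateBox") -> bool:
        return all(
            max(lo1, lo2) < min(hi1, hi2)
            for (lo1, hi1), (lo2, hi2) in zip(self.bounds, other.bounds)
        )


def _validate_gates(gates: Sequence[GateBox], n_axes: int | None = None) -> None:
    for g in gates:
        if n_axes is not None and g.n_axes != n_axes:
            raise ValueError(
                f"gate {g.label!r} has {g.n_axes} axes, events have {n_axes}"
            )
    for i, a in enumerate(gates):
        for b in gates[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(
                    f"gates {a.label!r} and {b.label!r} overlap; gates must be "
                    "pairwise disjoint"
                )


class GateClassifier(ClassifierMixin, BaseEstimator):
    """Rectangular-gate classifier; events in no gate get UNASSIGNED."""

    def __init__(self, gates: Sequence[GateBox] = ()):
        self.gates = gates

    def fit(self, X=None, y=None):
        n_axes = None
        if X is not None:
            X = check_array(X)
            n_axes = X.shape[1]
        _validate_gates(list(self.gates), n_axes)
        self.gates_ = list(self.gates)
        self.classes_ = np.array(
            [g.label for g in self.gates_] + [UNASSIGNED], dtype=object
        )
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "gates_")
        X = check_array(X)
        labels = np.full(X.shape[0], UNASSIGNED, dtype=object)
        for gate in self.gates_:
            inside = gate.contains(X)
            labels[inside & (labels == UNASSIGNED)] = gate.label
        return labels


def classify_gates(
    ratios: RatioTable | np.ndarray, gates: Sequence[GateBox]
) -> np.ndarray:
    """Gate labels (or UNASSIGNED) for log10 ratio coordinates."""
    X = _coords(ratios)
    return GateClassifier(gates).fit(X if len(X) else None).predict(X)


# ---------------------------------------------------------------------------
# reports


@dataclass
class SeparationReport:
    """Confusion matrix and summary metrics for a labelled classification.

    ``accuracy`` is computed over assigned events; the UNASSIGNED fraction
    is tracked separately.  ``recall`` counts unassigned events as misses.
    """

    confusion: pd.DataFrame  # rows = true, columns = assigned
    accuracy: float
    recall: pd.Series
    unassigned_fraction: float
    n_events: int

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "unassigned_fraction": self.unassigned_fraction,
            "n_events": self.n_events,
            "recall": self.recall.to_dict(),
            "confusion": {
                str(r): row.to_dict() for r, row in self.confusion.iterrows()
            },
        }


def separation_report(
    true_labels: Sequence, assigned_labels: Sequence
) -> SeparationReport:
    """Confusion matrix, accuracy, per-type recall and unassigned fraction."""
    true = np.asarray(true_labels, dtype=object)
    assigned = np.asarray(assigned_labels, dtype=object)
    if len(true) != len(assigned):
        raise ValueError(
            f"label lengths differ: {len(true)} true vs {len(assigned)} assigned"
        )
    n = len(true)
    confusion = pd.crosstab(
        pd.Series(true, name="true"), pd.Series(assigned, name="assigned")
    )
    is_assigned = assigned != UNASSIGNED
    correct = (true == assigned).sum()
    n_assigned = int(is_assigned.sum())
    accuracy = float(correct / n_assigned) if n_assigned else 0.0
    types = pd.unique(true)
    recall = pd.Series(
        {t: float(((true == t) & (assigned == t)).sum() / (true == t).sum()) for t in types}
    )
    return SeparationReport(
        confusion=confusion,
        accuracy=accuracy,
        recall=recall,
        unassigned_fraction=float((~is_assigned).sum() / n) if n else 0.0,
        n_events=n,
    )


# ---------------------------------------------------------------------------
# capacity


def estimate_capacity(
    dynamic_range_fold: float, peak_width_fold: float, n_axes: int = 1
) -> int:
    """How many cell types a ratio space can hold, by peak packing.

    Peak centers spaced at least ``peak_width_fold`` apart fit
    ``floor(log(D)/log(W)) + 1`` slots along an axis spanning a
    ``dynamic_range_fold`` range (both endpoints usable); independent axes
    multiply, giving ``slots ** n_axes`` distinguishable types.  This is the
    package's packing convention for the observation that a handful of
    reporters can in principle separate dozens to hundreds of cell types.
    """
    if dynamic_range_fold < 1:
        raise ValueError("dynamic range must be >= 1 fold")
    if peak_width_fold <= 1:
        raise ValueError("peak width must be > 1 fold")
    if n_axes not in (1, 2, 3):
        raise ValueError("n_axes must be 1, 2 or 3")
    slots = (
        int(math.floor(math.log(dynamic_range_fold) / math.log(peak_width_fold) + 1e-9))
        + 1
    )
    return slots**n_axes
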