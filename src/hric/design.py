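"""Sensor-set selection: log-ratio distances between cell types and
exhaustive min-distance ranking of 3- and 4-sensor panels.

Given a table of translational efficiencies ``T[miRNA, cell type]``, a panel
(x, y, z[, w]) with x on the denominator channel places cell type A at

    centroid_A = (log10(T_A(y)/T_A(x)), log10(T_A(z)/T_A(x))[, ...])

in (k-1)-dimensional log10 fluorescence-ratio space.  The distance between
two cell types is the Euclidean distance between their centroids, and a
panel's score is the *minimum* pairwise distance over the cell types to be
separated: the best panel maximises the worst-separated pair.  Absolute
uptake cancels in every coordinate, so rescaling one cell type's whole
efficiency column changes nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

Assignment = tuple[str, ...]


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an efficiency table (rows = miRNAs, columns = cell types)."""
    if table.index.has_duplicates or table.columns.has_duplicates:
        raise ValueError("efficiency table has duplicate miRNA or cell-type names")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("efficiency table has missing entries")
    if (values <= 0).any():
        raise ValueError("translational efficiencies must be > 0")
    return table


def _check_assignment(table: pd.DataFrame, assignment: Sequence[str]) -> Assignment:
    assignment = tuple(assignment)
    if len(set(assignment)) != len(assignment):
        raise ValueError(f"sensor assignment has duplicates: {assignment}")
    if not 3 <= len(assignment) <= 4:
        raise ValueError(f"assignment must have 3 or 4 sensors, got {len(assignment)}")
    missing = [m for m in assignment if m not in table.index]
    if missing:
        raise KeyError(f"miRNAs {missing} not in the efficiency table")
    return assignment


def centroid(
    table: pd.DataFrame, assignment: Sequence[str], cell_type: str
) -> np.ndarray:
    """Predicted position of ``cell_type`` in (k-1)-dim log10 ratio space.

    ``assignment[0]`` is the denominator-channel sensor; coordinate ``j`` is
    ``log10(T(sensor_{j+1}) / T(sensor_0))`` for that cell type.
    """
    assignment = _check_assignment(table, assignment)
    if cell_type not in table.columns:
        raise KeyError(
            f"cell type {cell_type!r} not in table (have: {list(table.columns)})"
        )
    col = table[cell_type]
    den = float(col.loc[assignment[0]])
    return np.array(
        [np.log10(float(col.loc[m]) / den) for m in assignment[1:]]
    )


def pair_distance(
    table: pd.DataFrame, assignment: Sequence[str], a: str, b: str
) -> float:
    """Euclidean log10-ratio distance d_A,B between two cell types."""
    if a == b:
        raise ValueError(f"pair_distance needs two distinct cell types, got {a!r}")
    ca = centroid(table, assignment, a)
    cb = centroid(table, assignment, b)
    return float(np.linalg.norm(ca - cb))


def score_set(
    table: pd.DataFrame, assignment: Sequence[str], cell_types: Sequence[str]
) -> float:
    """Minimum pairwise distance over all cell-type pairs (the panel score)."""
    if len(cell_types) < 2:
        raise ValueError("scoring needs >= 2 cell types")
    return min(
        pair_distance(table, assignment, a, b)
        for a, b in combinations(cell_types, 2)
    )


@dataclass
class DesignReport:
    """Ranked sensor panels with per-pair distances and predicted centroids."""

    table: pd.DataFrame  # columns: denominator, sensor_*, d_min, d(A|B)...
    cell_types: list[str]
    k: int
    n_candidates: int
    efficiency_table: pd.DataFrame

    def assignment(self, rank: int = 0) -> Assignment:
        row = self.table.iloc[rank]
        sensors = [row["denominator"]] + [
            row[f"sensor_{j}"] for j in range(1, self.k)
        ]
        return tuple(sensors)

    def centroids(self, rank: int = 0) -> dict[str, np.ndarray]:
        a = self.assignment(rank)
        return {
            ct: centroid(self.efficiency_table, a, ct) for ct in self.cell_types
        }

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "cell_types": self.cell_types,
            "n_candidates": self.n_candidates,
            "ranking": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def enumerate_sets(
    table: pd.DataFrame,
    k: int = 3,
    cell_types: Sequence[str] | None = None,
    top_n: int | None = None,
) -> DesignReport:
    """Exhaustively score every k-sensor panel and rank by min distance.

    The search space is every ordered choice of denominator times every
    unordered choice of the remaining k-1 sensors (coordinate permutations
    of the non-denominator sensors only permute axes and leave all distances
    unchanged, so they are deduplicated): ``m * C(m-1, k-1)`` candidates for
    m miRNAs.  Ties are broken by lexicographic miRNA-identifier order.
    """
    validate_table(table)
    if k not in (3, 4):
        raise ValueError(f"k must be 3 or 4, got {k}")
    mirnas = list(table.index)
    if k > len(mirnas):
        raise ValueError(f"k={k} exceeds the {len(mirnas)} miRNAs in the table")
    if cell_types is None:
        cell_types = list(table.columns)
    cell_types = list(cell_types)
    if len(cell_types) < 2:
        raise ValueError("need >= 2 cell types to separate")

    pairs = list(combinations(cell_types, 2))
    rows = []
    for den in mirnas:
        rest = sorted(m for m in mirnas if m != den)
        for others in combinations(rest, k - 1):
            assignment = (den,) + others
            dists = {
                f"d({a}|{b})": pair_distance(table, assignment, a, b)
                for a, b in pairs
            }
            row = {"denominator": den}
            row.update({f"sensor_{j}": m for j, m in enumerate(others, start=1)})
            row["d_min"] = min(dists.values())
            row.update(dists)
            rows.append(row)

    report = pd.DataFrame(rows)
    sort_cols = ["denominator"] + [f"sensor_{j}" for j in range(1, k)]
    report = report.sort_values(
        by=["d_min"] + sort_cols, ascending=[False] + [True] * len(sort_cols)
    ).reset_index(drop=True)
    n_candidates = len(report)
    if top_n is not None:
        report = report.head(top_n).reset_index(drop=True)
    return DesignReport(
        table=report,
        cell_types=cell_types,
        k=k,
        n_candidates=n_candidates,
        efficiency_table=table,
    )


def read_efficiency_table(path: str | Path) -> pd.DataFrame:
    """Read a miRNA x cell-type efficiency CSV (first column = miRNA ids)."""
    try:
        table = pd.read_csv(path, index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse efficiency table {path}: {exc}") from exc
    return validate_table(table)
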