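"""Synthetic example data: a translational-efficiency table and cell-type
profiles for the HeLa / 293FT / MCF-7 model system.

The real 20-miRNA efficiency measurements are not deposited as numbers, so
this module ships a *synthetic* stand-in table constructed to reproduce the
reported fold-relations between the lines: miR-24-3p is 1.3-fold more active
and miR-203a 1.5-fold less active in HeLa than in MCF-7, and no miRNA
differs by more than two-fold between HeLa and MCF-7.  Efficiencies are on
the control-normalised scale (no-target control = 1); a *lower* efficiency
means a *more active* miRNA.
"""

from __future__ import annotations

import pandas as pd

from .profiles import CellTypeProfile

CELL_TYPES = ("HeLa", "293FT", "MCF-7")

# rows: miRNA, columns: cell types.  Synthetic values; see module docstring.
_TABLE = {
    #                HeLa   293FT  MCF-7
    "miR-24-3p": (0.50, 0.80, 0.65),   # 0.65/0.50 = 1.3x more active in HeLa
    "miR-203a": (0.90, 0.55, 0.60),    # 0.90/0.60 = 1.5x less active in HeLa
    "miR-17-5p": (0.40, 0.70, 0.55),
    "miR-127-3p": (0.85, 0.45, 0.70),
    "miR-21-5p": (0.30, 0.35, 0.33),
    "miR-16-5p": (0.60, 0.62, 0.58),
}


def synthetic_efficiency_table() -> pd.DataFrame:
    """Synthetic miRNA x cell-type translational-efficiency table.

    Rows are miRNA identifiers, columns cell-type names, entries the
    translation retained by a sensor for that miRNA in that cell type.
    """
    return pd.DataFrame.from_dict(
        _TABLE, orient="index", columns=list(CELL_TYPES)
    ).rename_axis("miRNA")


def profiles_from_table(
    table: pd.DataFrame | None = None,
) -> list[CellTypeProfile]:
    """Cell-type profiles whose knockdown maps are the table's columns."""
    if table is None:
        table = synthetic_efficiency_table()
    return [
        CellTypeProfile(name=ct, knockdown=table[ct].to_dict())
        for ct in table.columns
    ]
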