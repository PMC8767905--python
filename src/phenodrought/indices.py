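"""Yield-based drought tolerance indices.

Every index is a function of a genotype's grain yield per plant under
unstressed (``Yp``) and drought-stressed (``Ys``) treatments, plus two
cohort-level constants: the grand means ``Yp_bar``/``Ys_bar`` over all
genotypes in the trial and the stress intensity ``SI = 1 - Ys_bar/Yp_bar``.

Implemented indices and their tolerance direction:

========  =======================================  ==========================
name      formula                                  "better" means
========  =======================================  ==========================
TOL_diff  Yp - Ys                                  low (absolute yield loss)
TOL_pct   100 (Yp - Ys) / Yp                       low (percent yield loss)
MP        (Yp + Ys) / 2                            high
GMP       sqrt(Yp * Ys)                            high
SSI       (1 - Ys/Yp) / SI                         low
STI       Yp * Ys / Yp_bar**2                      high
YI        Ys / Ys_bar                              high
YSI       Ys / Yp                                  high
RT        100 (Yp - Ys) / Ys                       low
RDY       1 - Ys/Yp                                low (relative yield drop)
========  =======================================  ==========================

The tolerance index appears in the literature both as the yield difference
in grams and as a percentage of Yp; published per-genotype tables almost
always print the gram-scale difference, so ``TOL_diff`` is the default used
for rankings and check comparisons, with ``TOL_pct`` computed alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CohortConstants",
    "INDEX_DIRECTION",
    "grand_means",
    "index_row",
    "index_table",
    "compare_to_checks",
    "summarize_index",
]

#: direction in which an index signals tolerance: True = lower is better
LOWER_IS_BETTER = {
    "TOL_diff": True,
    "TOL_pct": True,
    "SSI": True,
    "RT": True,
    "RDY": True,
    "MP": False,
    "GMP": False,
    "STI": False,
    "YI": False,
    "YSI": False,
}
INDEX_DIRECTION = {k: ("low" if v else "high") for k, v in LOWER_IS_BETTER.items()}

INDEX_COLUMNS = ["TOL_diff", "TOL_pct", "MP", "GMP", "SSI", "STI", "YI", "YSI", "RT", "RDY"]


@dataclass(frozen=True)
class CohortConstants:
    """Cohort-level constants entering SSI, STI and YI.

    yp_bar, ys_bar : grand mean yields (g/plant) over all genotypes in the
        table, checks included; si : stress intensity 1 - ys_bar/yp_bar.
    """

    yp_bar: float
    ys_bar: float
    si: float


def _require_yields(df: pd.DataFrame) -> pd.DataFrame:
    if not {"Yp", "Ys"}.issubset(df.columns):
        raise ValueError("yield table must have 'Yp' and 'Ys' columns")
    missing = df[df["Yp"].isna() | df["Ys"].isna()]
    if len(missing):
        names = ", ".join(map(str, missing.get("genotype", missing.index)))
        warnings.warn(f"dropping genotypes with missing yield: {names}")
        df = df.drop(missing.index)
    if df.empty:
        raise ValueError("no genotype has both Yp and Ys")
    return df


def grand_means(yields: pd.DataFrame) -> CohortConstants:
    """Grand mean yields and stress intensity over *all* supplied rows.

    Checks (parents) are included deliberately: the printed per-genotype
    index values in multi-check trials are only recovered when the grand
    means span the full table.
    """
    df = _require_yields(yields)
    yp_bar = float(df["Yp"].mean())
    ys_bar = float(df["Ys"].mean())
    if yp_bar <= 0:
        raise ValueError("grand mean unstressed yield must be positive")
    return CohortConstants(yp_bar=yp_bar, ys_bar=ys_bar, si=1.0 - ys_bar / yp_bar)


def index_row(yp: float, ys: float, constants: CohortConstants) -> dict[str, float]:
    """All drought indices for one genotype.

    SSI is undefined (NaN) when the cohort experienced no stress (SI <= 0).
    ``ys > yp`` is computed as-is but flagged via a warning, since a stressed
    yield above the unstressed one usually indicates a data problem.
    """
    if yp <= 0:
        raise ValueError(f"Yp must be positive, got {yp}")
    if ys < 0:
        raise ValueError(f"Ys must be non-negative, got {ys}")
    if ys > yp:
        warnings.warn(f"Ys={ys} exceeds Yp={yp}; indices computed as-is")
    ysi = ys / yp
    rdy = 1.0 - ysi
    row = {
        "TOL_diff": yp - ys,
        "TOL_pct": 100.0 * rdy,
        "MP": 0.5 * (yp + ys),
        "GMP": float(np.sqrt(yp * ys)),
        "SSI": rdy / constants.si if constants.si > 0 else float("nan"),
        "STI": yp * ys / constants.yp_bar**2,
        "YI": ys / constants.ys_bar if constants.ys_bar > 0 else float("nan"),
        "YSI": ysi,
        "RT": 100.0 * (yp - ys) / ys if ys > 0 else float("inf") if yp > ys else 0.0,
        "RDY": rdy,
    }
    return row


def index_table(yields: pd.DataFrame) -> tuple[pd.DataFrame, CohortConstants]:
    """Compute the full index table for a cohort.

    Parameters
    ----------
    yields : DataFrame with columns ``genotype``, ``Yp``, ``Ys`` and
        optionally ``role`` (NIL/RP/DP/CHECK).

    Returns
    -------
    (table, constants) : the input rows with one column per index appended,
        and the cohort constants used.
    """
    df = _require_yields(yields).copy()
    constants = grand_means(df)
    computed = pd.DataFrame(
        [index_row(yp, ys, constants) for yp, ys in zip(df["Yp"], df["Ys"])],
        index=df.index,
    )
    for col in INDEX_COLUMNS:
        df[f"{col}_calc"] = computed[col]
    return df, constants


def _better(a: pd.Series, ref: float, index: str) -> pd.Series:
    """Strict 'better than ref' in the index's tolerance direction."""
    return a < ref if LOWER_IS_BETTER[index] else a > ref


def compare_to_checks(
    table: pd.DataFrame,
    rp_id: str,
    dp_id: str,
    indices: Iterable[str] = ("TOL_diff", "MP", "GMP", "SSI", "STI", "YI", "YSI", "RT", "RDY"),
    printed_columns: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Count NILs strictly better than each check, per index.

    Ties never count as better. By default comparisons use the recomputed
    ``*_calc`` columns; ``printed_columns`` maps an index name to a column
    of values printed in a source table, used instead for that index —
    published counts can hinge on the source's own rounding (a printed tie
    is a tie even when the unrounded values would differ).
    """
    if "role" not in table.columns:
        raise ValueError("table must carry a 'role' column to locate checks")
    printed_columns = dict(printed_columns or {})

    def pick(index: str) -> pd.Series:
        col = printed_columns.get(index, f"{index}_calc")
        if col not in table.columns:
            raise KeyError(f"column {col!r} not present for index {index}")
        return table[col]

    rows = []
    for check_id, label in ((rp_id, "vs_RP"), (dp_id, "vs_DP")):
        hit = table["genotype"] == check_id
        if not hit.any():
            raise ValueError(f"check genotype {check_id!r} not in table")
        for index in indices:
            values = pick(index)
            ref = float(values[hit].iloc[0])
            nils = table["role"] == "NIL"
            rows.append(
                {
                    "index": index,
                    "comparison": label,
                    "check": check_id,
                    "direction": INDEX_DIRECTION[index],
                    "n_better": int(_better(values[nils], ref, index).sum()),
                    "n_nil": int(nils.sum()),
                }
            )
    return pd.DataFrame(rows)


def summarize_index(table: pd.DataFrame, index: str, column: str | None = None) -> dict:
    """min/max/mean and extreme genotypes of one index over NIL rows only."""
    if index not in LOWER_IS_BETTER:
        raise KeyError(f"unknown index {index!r}")
    col = column or f"{index}_calc"
    if col not in table.columns:
        raise KeyError(f"column {col!r} not in table")
    nils = table[table["role"] == "NIL"]
    if nils.empty:
        raise ValueError("no NIL rows to summarize")
    values = nils[col].astype(float)
    return {
        "index": index,
        "min": float(values.min()),
        "max": float(values.max()),
        "mean": float(values.mean()),
        "argmin": str(nils.loc[values.idxmin(), "genotype"]),
        "argmax": str(nils.loc[values.idxmax(), "genotype"]),
    }
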