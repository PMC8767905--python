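"""Packaged per-genotype yield/index tables.

Two small CSVs ship with the package, transcribed from a published rice
NIL drought trial (35 Pusa 44 NILs carrying qDTY2.1 + qDTY3.1, plus the
recurrent parent Pusa 44 and the donor parent IR81896-B-B-142):

- ``field_yield_table`` — field-trial yield per plant (g) under the two
  treatments with the published drought indices (TOL in grams, MP, GMP,
  SSI, STI, YI, YSI) as printed, at the source's rounding.
- ``pot_yield_table`` — pot-culture yields with the published relative
  yield drop (RDY) and relative tolerance (RT) columns.

The printed index columns are retained alongside the yields so recomputed
values can be checked cell-by-cell against the source.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

RP_ID = "Pusa 44"
DP_ID = "IR81896-B-B-142"

__all__ = ["field_yield_table", "pot_yield_table", "RP_ID", "DP_ID"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("phenodrought.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def field_yield_table() -> pd.DataFrame:
    """37-row field trial table: genotype, role, Yp, Ys + printed indices."""
    return _load("table4_field.csv")


def pot_yield_table() -> pd.DataFrame:
    """37-row pot trial table: genotype, role, Yp, Ys + printed RDY/RT."""
    return _load("table3_pot.csv")
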