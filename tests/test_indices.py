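"""Drought index formulas, cohort constants and check comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenodrought import indices
from phenodrought.datasets import DP_ID, RP_ID

yields = st.floats(min_value=0.5, max_value=100.0, allow_nan=False)


def make_constants(yp_bar=24.69, ys_bar=16.62):
    return indices.CohortConstants(yp_bar=yp_bar, ys_bar=ys_bar, si=1 - ys_bar / yp_bar)


class TestGrandMeans:
    def test_single_row(self):
        c = indices.grand_means(pd.DataFrame({"Yp": [10.0], "Ys": [5.0]}))
        assert (c.yp_bar, c.ys_bar, c.si) == (10.0, 5.0, 0.5)

    def test_no_stress_gives_zero_si(self):
        df = pd.DataFrame({"Yp": [10.0, 20.0], "Ys": [10.0, 20.0]})
        assert indices.grand_means(df).si == 0.0

    def test_field_table_constants(self, field_table):
        """Grand means of the packaged field table match the column sums."""
        c = indices.grand_means(field_table)
        assert c.yp_bar == pytest.approx(24.692, abs=0.001)
        assert c.ys_bar == pytest.approx(16.619, abs=0.001)
        assert c.si == pytest.approx(0.327, abs=0.001)

    def test_missing_yield_dropped_with_warning(self):
        df = pd.DataFrame(
            {"genotype": ["a", "b"], "Yp": [10.0, np.nan], "Ys": [5.0, 4.0]}
        )
        with pytest.warns(UserWarning, match="b"):
            c = indices.grand_means(df)
        assert c.yp_bar == 10.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            indices.grand_means(pd.DataFrame({"Yp": [], "Ys": []}))


class TestIndexRow:
    def test_no_stress_effect_identity(self):
        row = indices.index_row(10.0, 10.0, make_constants())
        assert row["TOL_diff"] == 0
        assert row["YSI"] == 1.0
        assert row["RT"] == 0
        assert row["RDY"] == 0
        assert row["SSI"] == 0
        assert row["MP"] == row["GMP"] == 10.0

    def test_recurrent_parent_row(self, field_table):
        """Pusa 44's published row from its printed yields."""
        c = indices.grand_means(field_table)
        row = indices.index_row(22.2, 10.9, c)
        assert row["TOL_diff"] == pytest.approx(11.3, abs=0.05)
        assert row["MP"] == pytest.approx(16.55, abs=0.05)
        assert row["GMP"] == pytest.approx(15.56, abs=0.05)
        assert row["SSI"] == pytest.approx(1.56, abs=0.02)
        assert row["STI"] == pytest.approx(0.40, abs=0.02)
        assert row["YI"] == pytest.approx(0.66, abs=0.02)
        assert row["YSI"] == pytest.approx(0.49, abs=0.02)

    def test_donor_parent_row(self, field_table):
        c = indices.grand_means(field_table)
        row = indices.index_row(22.4, 15.2, c)
        assert row["SSI"] == pytest.approx(0.98, abs=0.02)
        assert row["STI"] == pytest.approx(0.56, abs=0.02)

    def test_pot_rdy_rt_row(self):
        row = indices.index_row(13.0, 7.5, make_constants())
        assert row["RDY"] == pytest.approx(0.42, abs=0.01)
        assert row["RT"] == pytest.approx(73.3, abs=0.1)

    def test_nonpositive_yp_raises(self):
        with pytest.raises(ValueError):
            indices.index_row(0.0, 1.0, make_constants())

    def test_ys_above_yp_flagged(self):
        with pytest.warns(UserWarning):
            row = indices.index_row(5.0, 6.0, make_constants())
        assert row["RDY"] < 0

    @settings(max_examples=200, deadline=None)
    @given(yp=yields, ys=yields)
    def test_algebraic_identities(self, yp, ys):
        """AM>=GM, YSI/RDY/TOL/RT identities and SSI*SI = 1-YSI."""
        ys = min(ys, yp)
        c = make_constants()
        r = indices.index_row(yp, ys, c)
        assert r["MP"] + 1e-9 >= r["GMP"]
        assert r["YSI"] == pytest.approx(ys / yp, abs=1e-12)
        assert r["RDY"] == pytest.approx(1 - r["YSI"], abs=1e-12)
        assert r["TOL_diff"] == pytest.approx(yp - ys, abs=1e-12)
        assert r["SSI"] * c.si == pytest.approx(1 - r["YSI"], abs=1e-9)
        assert r["GMP"] ** 2 == pytest.approx(yp * ys, rel=1e-12)
        assert r["STI"] * c.yp_bar**2 == pytest.approx(yp * ys, rel=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(yp=yields, ys=yields, scale=st.floats(min_value=0.1, max_value=10.0))
    def test_scale_equivariance(self, yp, ys, scale):
        """Scaling every yield by c leaves ratio indices unchanged and
        scales gram-scale indices by c."""
        ys = min(ys, yp)
        c1 = make_constants(20.0, 15.0)
        c2 = make_constants(20.0 * scale, 15.0 * scale)
        a = indices.index_row(yp, ys, c1)
        b = indices.index_row(yp * scale, ys * scale, c2)
        for ratio in ("SSI", "STI", "YI", "YSI", "TOL_pct", "RT", "RDY"):
            assert b[ratio] == pytest.approx(a[ratio], rel=1e-9, abs=1e-12)
        for gram in ("TOL_diff", "MP", "GMP"):
            assert b[gram] == pytest.approx(a[gram] * scale, rel=1e-9, abs=1e-12)

    def test_ssi_rank_equals_rdy_rank(self):
        """Ordering by SSI coincides with ordering by 1 - YSI for fixed SI."""
        rng = np.random.default_rng(0)
        c = make_constants()
        rows = [indices.index_row(yp, min(ys, yp), c)
                for yp, ys in rng.uniform(1, 50, (30, 2))]
        ssi = np.array([r["SSI"] for r in rows])
        rdy = np.array([r["RDY"] for r in rows])
        assert (np.argsort(ssi) == np.argsort(rdy)).all()


class TestIndexTable:
    def test_field_table_counts(self, field_table):
        """Published check-comparison counts from the field table."""
        table, _ = indices.index_table(field_table)
        counts = indices.compare_to_checks(
            table, RP_ID, DP_ID, printed_columns={"TOL_diff": "TOL"}
        )
        get = lambda idx, cmp: counts.set_index(["index", "comparison"]).loc[
            (idx, cmp), "n_better"
        ]
        assert get("TOL_diff", "vs_RP") == 29
        assert get("TOL_diff", "vs_DP") == 16
        assert get("STI", "vs_RP") == 32
        assert get("MP", "vs_DP") == 27
        assert get("YI", "vs_DP") == 24
        assert 35 - get("SSI", "vs_RP") == 5  # exactly five NILs not below RP

    def test_pot_table_rdy(self, pot_table):
        table, _ = indices.index_table(pot_table)
        nil = table[table["role"] == "NIL"]
        assert nil["RDY_calc"].mean() == pytest.approx(0.34, abs=0.01)
        assert nil["RDY_calc"].min() == 0.0

    def test_ties_not_counted_as_better(self):
        df = pd.DataFrame(
            {
                "genotype": ["rp", "dp", "n1", "n2"],
                "role": ["RP", "DP", "NIL", "NIL"],
                "Yp": [10.0] * 4,
                "Ys": [5.0] * 4,
            }
        )
        table, _ = indices.index_table(df)
        counts = indices.compare_to_checks(table, "rp", "dp")
        assert (counts["n_better"] == 0).all()

    def test_missing_check_raises(self, field_table):
        table, _ = indices.index_table(field_table)
        with pytest.raises(ValueError, match="nope"):
            indices.compare_to_checks(table, "nope", DP_ID)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            indices.index_table(pd.DataFrame({"Yp": [], "Ys": []}))


class TestSummarize:
    def test_lowest_tol_genotype(self, field_table):
        table, _ = indices.index_table(field_table)
        s = indices.summarize_index(table, "TOL_diff")
        assert s["argmin"] == "P1823-12-114"
        assert s["min"] == pytest.approx(1.45, abs=0.1)

    def test_pot_rdy_minimum(self, pot_table):
        table, _ = indices.index_table(pot_table)
        s = indices.summarize_index(table, "RDY")
        assert s["argmin"] == "P1823-12-89"
        assert s["min"] == 0.0

    def test_constant_column(self):
        df = pd.DataFrame(
            {"genotype": ["a", "b"], "role": ["NIL", "NIL"], "Yp": [10.0, 10.0], "Ys": [5.0, 5.0]}
        )
        table, _ = indices.index_table(df)
        s = indices.summarize_index(table, "MP")
        assert s["min"] == s["max"] == s["mean"]

    def test_unknown_index_raises(self, field_table):
        table, _ = indices.index_table(field_table)
        with pytest.raises(KeyError):
            indices.summarize_index(table, "NOPE")
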