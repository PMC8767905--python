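"""Stage changes, CV, variance ratios, trend classes, scoring, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodrought import analysis, cohort as cm


class TestStageChange:
    def test_signed_percent_change(self):
        assert analysis.stage_change_pct(100.0, 80.0) == -20.0
        assert analysis.stage_change_pct(100.0, 100.0) == 0.0
        assert analysis.stage_change_pct(167.56, 185.62) == pytest.approx(10.78, abs=0.01)

    def test_zero_baseline_raises(self):
        with pytest.raises(ZeroDivisionError):
            analysis.stage_change_pct(0.0, 1.0)

    def test_stage_changes_table(self, default_trajectories):
        changes = analysis.stage_changes(default_trajectories)
        assert set(changes["phase"]) == {"decline", "recovery"}
        assert changes["defined"].all()


class TestCVAndVarianceRatio:
    def test_cv_basic(self):
        assert analysis.trajectory_cv([10.0, 10.0, 10.0]) == 0.0
        assert analysis.trajectory_cv([10.0, 20.0, 30.0]) == pytest.approx(50.0)

    def test_cv_scale_invariant(self):
        v = [3.0, 5.0, 9.0, 4.0]
        assert analysis.trajectory_cv(v) == pytest.approx(
            analysis.trajectory_cv([10 * x for x in v])
        )

    def test_cv_errors(self):
        with pytest.raises(ValueError):
            analysis.trajectory_cv([1.0])
        with pytest.raises(ZeroDivisionError):
            analysis.trajectory_cv([-1.0, 1.0])

    def test_variance_ratio(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert analysis.variance_ratio(a, a) == 1.0
        doubled = [2 * x for x in a]
        assert analysis.variance_ratio(doubled, a) == pytest.approx(4.0)

    def test_variance_ratio_equal_sigma_near_one(self):
        rng = np.random.default_rng(7)
        s, u = rng.normal(0, 1, 200), rng.normal(0, 1, 200)
        assert 0.7 <= analysis.variance_ratio(s, u) <= 1.4

    def test_variance_ratio_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            analysis.variance_ratio([1.0, 2.0], [3.0, 3.0])


class TestClassifyTrend:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ((100, 99, 98, 99, 100), "stable"),
            ((100, 80, 60, 75, 90), "decline_recovery"),
            ((100, 80, 60, 55, 50), "decline"),
        ],
    )
    def test_three_classes(self, series, expected):
        assert analysis.classify_trend(series, flat_tol_pct=10.0) == expected

    def test_missing_stage_raises(self):
        with pytest.raises(ValueError):
            analysis.classify_trend([100, 90, 80, 70])


class TestCompositeScore:
    def test_best_on_every_component_ranks_first(self):
        rows = []
        # genotype "best" dominates every component
        for geno, psa_d, nir_d, wu_d, tr_d, psa_r in [
            ("best", -1.0, 1.0, -60.0, -50.0, 30.0),
            ("mid", -15.0, 8.0, -40.0, -30.0, 10.0),
            ("worst", -30.0, 14.0, -20.0, -10.0, 2.0),
        ]:
            for trait, phase, v in [
                ("PSA", "decline", psa_d),
                ("NIR", "decline", nir_d),
                ("WU", "decline", wu_d),
                ("TR", "decline", tr_d),
                ("PSA", "recovery", psa_r),
                ("NIR", "recovery", -2.0),
                ("WU", "recovery", 10.0),
                ("TR", "recovery", 10.0),
            ]:
                rows.append(
                    {"genotype": geno, "treatment": "stressed", "trait": trait,
                     "phase": phase, "pct_change": v}
                )
        scores = analysis.composite_tolerance_score(pd.DataFrame(rows), k=1)
        best = scores.set_index("genotype")
        assert best.loc["best", "composite_rank"] == 1
        assert bool(best.loc["best", "selected"])
        assert not best.loc["worst", "selected"]

    def test_noiseless_composite_orders_by_tau(self, noiseless_cohort, noiseless_config):
        """With no noise the composite ordering equals descending tau."""
        traj = cm.simulate_trajectories(noiseless_cohort, noiseless_config)
        changes = analysis.stage_changes(traj)
        scores = analysis.composite_tolerance_score(changes)
        taus = {g.id: g.tau for g in noiseless_cohort}
        merged = scores.assign(tau=scores["genotype"].map(taus)).sort_values("composite_rank")
        assert (merged["tau"].diff().dropna() <= 1e-12).all()

    def test_default_noise_recovers_tau_ranking(self, default_cohort, default_config):
        """Spearman(composite rank, tau rank) >= 0.8 under default noise."""
        traj = cm.simulate_trajectories(default_cohort, default_config)
        scores = analysis.composite_tolerance_score(analysis.stage_changes(traj))
        taus = {g.id: g.tau for g in default_cohort}
        rho = stats.spearmanr(
            scores["composite_rank"], [-taus[g] for g in scores["genotype"]]
        ).statistic
        assert rho >= 0.8

    def test_selection_sensitivity_over_seeds(self):
        """>= 80 % of the true top-k tau genotypes are selected on average."""
        hits = []
        for seed in range(20):
            cfg = cm.CohortConfig(seed=seed)
            cohort = cm.make_cohort(cfg)
            traj = cm.simulate_trajectories(cohort, cfg)
            scores = analysis.composite_tolerance_score(analysis.stage_changes(traj), k=9)
            taus = pd.Series({g.id: g.tau for g in cohort})
            true_top = set(taus.nlargest(9).index)
            chosen = set(scores.loc[scores["selected"], "genotype"])
            hits.append(len(true_top & chosen) / 9)
        assert np.mean(hits) >= 0.8

    def test_monotone_rescaling_invariance(self, noiseless_cohort, noiseless_config):
        """Rank-based score is unchanged by monotone rescaling of one trait."""
        traj = cm.simulate_trajectories(noiseless_cohort, noiseless_config)
        changes = analysis.stage_changes(traj)
        a = analysis.composite_tolerance_score(changes)
        scaled = changes.copy()
        wu = scaled["trait"] == "WU"
        scaled.loc[wu, "pct_change"] = scaled.loc[wu, "pct_change"] * 3.0 + 7.0
        b = analysis.composite_tolerance_score(scaled)
        assert (a["composite_rank"] == b["composite_rank"]).all()

    def test_missing_trait_raises(self):
        rows = pd.DataFrame(
            [{"genotype": "a", "treatment": "stressed", "trait": "PSA",
              "phase": "decline", "pct_change": -5.0}]
        )
        with pytest.raises(ValueError):
            analysis.composite_tolerance_score(rows)


class TestStagewiseCorrelation:
    def make_traits(self, values_by_geno, trait="PSA", stage="III"):
        return pd.DataFrame(
            [
                {"genotype": g, "treatment": "stressed", "stage": stage,
                 "trait": trait, "value": v}
                for g, v in values_by_geno.items()
            ]
        )

    def test_exact_linear_pair(self):
        traits = self.make_traits({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        responses = pd.DataFrame({"genotype": list("abcd"), "Yp": [2.0, 4.0, 6.0, 8.0]})
        grid = analysis.stagewise_correlation(traits, responses)
        assert grid["r"].iloc[0] == pytest.approx(1.0)

    def test_anti_linear_pair(self):
        traits = self.make_traits({"a": 1.0, "b": 2.0, "c": 3.0})
        responses = pd.DataFrame({"genotype": list("abc"), "Yp": [3.0, 2.0, 1.0]})
        grid = analysis.stagewise_correlation(traits, responses)
        assert grid["r"].iloc[0] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=20), rng.normal(size=20)
        traits = self.make_traits({f"g{i}": x[i] for i in range(20)})
        responses = pd.DataFrame({"genotype": [f"g{i}" for i in range(20)], "Yp": y})
        grid = analysis.stagewise_correlation(traits, responses)
        manual = np.cov(x, y, ddof=1)[0, 1] / (np.std(x, ddof=1) * np.std(y, ddof=1))
        assert grid["r"].iloc[0] == pytest.approx(manual, abs=1e-12)

    def test_symmetry_under_role_swap(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=15), rng.normal(size=15)
        genos = [f"g{i}" for i in range(15)]
        t1 = self.make_traits(dict(zip(genos, x)))
        r1 = pd.DataFrame({"genotype": genos, "resp": y})
        t2 = self.make_traits(dict(zip(genos, y)))
        r2 = pd.DataFrame({"genotype": genos, "resp": x})
        g1 = analysis.stagewise_correlation(t1, r1)
        g2 = analysis.stagewise_correlation(t2, r2)
        assert g1["r"].iloc[0] == pytest.approx(g2["r"].iloc[0], abs=1e-12)

    def test_small_n_flagged_missing(self):
        traits = self.make_traits({"a": 1.0, "b": 2.0})
        responses = pd.DataFrame({"genotype": ["a", "b"], "Yp": [1.0, 2.0]})
        grid = analysis.stagewise_correlation(traits, responses)
        assert grid["missing"].iloc[0]
        assert np.isnan(grid["r"].iloc[0])
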