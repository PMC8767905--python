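"""Stage-wise temporal analysis and tolerance ranking.

The drought episode has two phases: decline (stage I -> III, progressive
soil drying) and recovery (stage III -> V, after lifesaving irrigation).
Percent changes over these phases summarize each genotype's response; a
rank-based composite score orders genotypes by the pattern a tolerant line
shows — stable PSA, a small NIR rise, strong water-saving (WU and TR cuts)
during decline, and fast PSA recovery — and Pearson correlations relate
stage-wise traits to yield and to the yield-based tolerance indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("I", "II", "III", "IV", "V")
PHASES = {"decline": ("I", "III"), "recovery": ("III", "V")}

__all__ = [
    "stage_change_pct",
    "stage_changes",
    "trajectory_cv",
    "variance_ratio",
    "classify_trend",
    "composite_tolerance_score",
    "stagewise_correlation",
]


def stage_change_pct(v_start: float, v_end: float) -> float:
    """Signed percent change 100 * (v_end - v_start) / v_start."""
    if v_start == 0:
        raise ZeroDivisionError("percent change undefined for a zero baseline")
    return 100.0 * (v_end - v_start) / v_start


def stage_changes(traj: pd.DataFrame) -> pd.DataFrame:
    """Per-genotype/treatment/trait percent change for both phases.

    Input is the long trait table (genotype, treatment, stage, trait,
    value); rows with a zero baseline are emitted with NaN and flagged.
    """
    wide = traj.pivot_table(
        index=["genotype", "treatment", "trait"], columns="stage", values="value"
    )
    rows = []
    for (genotype, treatment, trait), stages in wide.iterrows():
        for phase, (s0, s1) in PHASES.items():
            v0, v1 = stages.get(s0, np.nan), stages.get(s1, np.nan)
            ok = pd.notna(v0) and pd.notna(v1) and v0 != 0
            rows.append(
                {
                    "genotype": genotype,
                    "treatment": treatment,
                    "trait": trait,
                    "phase": phase,
                    "pct_change": stage_change_pct(v0, v1) if ok else np.nan,
                    "defined": bool(ok),
                }
            )
    return pd.DataFrame(rows)


def trajectory_cv(values) -> float:
    """Coefficient of variation across stages, % (sample sd, n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV needs at least two stage values")
    mean = v.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined for a zero mean")
    return 100.0 * v.std(ddof=1) / mean


def variance_ratio(stress_values, unstress_values) -> float:
    """Vs/Vus: ratio of sample variances between treatments."""
    s = np.asarray(stress_values, dtype=float)
    u = np.asarray(unstress_values, dtype=float)
    if s.size < 2 or u.size < 2:
        raise ValueError("need >= 2 values per group")
    vu = u.var(ddof=1)
    if vu == 0:
        raise ZeroDivisionError("unstressed variance is zero; ratio undefined")
    return float(s.var(ddof=1) / vu)


def classify_trend(series, flat_tol_pct: float = 10.0) -> str:
    """Label a five-stage series: stable / decline_recovery / decline.

    Stable means the I->III change stays within +-flat_tol_pct (a flat
    curve signalling endurance); otherwise the series either regains
    ground by stage V (decline_recovery) or keeps falling (decline).
    """
    v = np.asarray(series, dtype=float)
    if v.size != 5 or np.isnan(v).any():
        raise ValueError("need five stage values (I..V) with no gaps")
    change = stage_change_pct(v[0], v[2])
    if abs(change) <= flat_tol_pct:
        return "stable"
    if v[4] >= v[2]:
        return "decline_recovery"
    return "decline"


#: (trait, phase, transform of pct_change, higher-rank-is-better) per component
_COMPONENTS = {
    "psa_retention": ("PSA", "decline", abs, False),  # smallest |PSA decline|
    "nir_stability": ("NIR", "decline", None, False),  # smallest NIR increase
    "wu_reduction": ("WU", "decline", None, False),  # most negative WU change
    "tr_reduction": ("TR", "decline", None, False),  # most negative TR change
    "recovery_speed": ("PSA", "recovery", None, True),  # largest PSA regain
}


def composite_tolerance_score(
    changes: pd.DataFrame, k: int = 9, treatment: str = "stressed"
) -> pd.DataFrame:
    """Unweighted mean-rank tolerance score over five response components.

    Ranks (1 = best, average ranks on ties) are taken over all genotypes
    jointly for: smallest |PSA decline|, smallest NIR rise, largest WU
    reduction, largest TR reduction, and fastest PSA recovery. ``selected``
    flags the k best composite ranks.
    """
    sub = changes[changes["treatment"] == treatment]
    wide = sub.pivot_table(index="genotype", columns=["trait", "phase"], values="pct_change")
    ranks = {}
    for name, (trait, phase, transform, descending) in _COMPONENTS.items():
        if (trait, phase) not in wide.columns:
            raise ValueError(f"missing stage changes for trait {trait!r}, phase {phase!r}")
        values = wide[(trait, phase)].astype(float)
        if values.isna().any():
            raise ValueError(f"undefined percent change for component {name!r}")
        scores = values.abs() if transform is abs else values
        ranks[name] = pd.Series(
            stats.rankdata(-scores if descending else scores, method="average"),
            index=wide.index,
        )
    out = pd.DataFrame(ranks)
    out["composite"] = out.mean(axis=1)
    order = stats.rankdata(out["composite"], method="average")
    out["composite_rank"] = order
    out["selected"] = order <= k
    return out.reset_index()


def stagewise_correlation(
    traits: pd.DataFrame,
    responses: pd.DataFrame,
    treatment: str = "stressed",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson r between each stage-wise trait and each response variable.

    traits: long table (genotype, treatment, stage, trait, value);
    responses: one row per genotype, one column per response (yield or
    index). Cells with fewer than 3 paired observations are flagged
    missing. Significance stars are per-cell two-sided t-tests at alpha,
    with no multiplicity correction.
    """
    response_cols = [c for c in responses.columns if c not in ("genotype", "role")]
    sub = traits[traits["treatment"] == treatment]
    rows = []
    for (stage, trait), group in sub.groupby(["stage", "trait"], sort=False):
        merged = group.merge(responses, on="genotype", how="inner")
        for resp in response_cols:
            paired = merged[["value", resp]].dropna()
            n = len(paired)
            if n < 3 or paired["value"].nunique() < 2 or paired[resp].nunique() < 2:
                rows.append(
                    {"stage": stage, "trait": trait, "response": resp, "r": np.nan,
                     "n": n, "p": np.nan, "significant": False, "missing": True}
                )
                continue
            r, p = stats.pearsonr(paired["value"], paired[resp])
            rows.append(
                {"stage": stage, "trait": trait, "response": resp, "r": float(r),
                 "n": n, "p": float(p), "significant": bool(p < alpha), "missing": False}
            )
    return pd.DataFrame(rows)
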