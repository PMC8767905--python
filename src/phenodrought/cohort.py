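"""Synthetic drought-phenomics cohort generator.

Emulates a controlled-environment reproductive-stage drought experiment on
a rice NIL panel: ~35 near-isogenic lines plus the recurrent parent (RP,
drought-sensitive) and the donor parent (DP, QTL source), each grown under
a stressed and an unstressed treatment, imaged at five stages (days 0, 5,
10, 12, 15 — progressive drought to stage III, lifesaving irrigation after
day 11, recovery through stage V), with daily gravimetric pot weighing
against plant-free mock pots.

Every genotype carries a latent drought-tolerance scalar tau in [0, 1].
tau drives everything monotonically: relative yield drop under stress
(RDY) falls linearly with tau; PSA shrinkage and NIR brightening under
peak drought scale with (1 - tau); the water-saving responses — WU and TR
reduction — and the speed of post-irrigation recovery scale with tau.
Cohort-level stage means are anchored to published glasshouse dynamics
(TR 0.072 -> 0.036 -> 0.063 g/cm2, NIR gray 167.56 -> 185.62 -> 180.54
under stress), so downstream extraction and ranking can be validated
against known ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .gravimetric import PotGeometry

__all__ = [
    "Genotype",
    "TraitAnchors",
    "CohortConfig",
    "make_cohort",
    "simulate_yields",
    "simulate_trajectories",
    "simulate_pot_weights",
    "write_dataset",
]

STAGES = ("I", "II", "III", "IV", "V")
TRAITS = ("PSA", "WU", "TR", "NIR")


@dataclass(frozen=True)
class Genotype:
    id: str
    role: str  # NIL | RP | DP | CHECK
    tau: float  # latent drought tolerance in [0, 1]


@dataclass(frozen=True)
class TraitAnchors:
    """Cohort-mean anchor values the stressed trajectories must reproduce.

    Stage-I bases and the I->III / III->V dynamics are cohort means from
    glasshouse observation; per-genotype heterogeneity is spread around
    them by tau.
    """

    nir_unstressed: tuple[float, float] = (166.81, 180.7)  # stage I -> V drift
    nir_stressed: tuple[float, float, float] = (167.56, 185.62, 180.54)  # I, III, V
    tr_stressed: tuple[float, float, float] = (0.072, 0.036, 0.063)  # g/cm2/day
    psa_decline_range: tuple[float, float] = (0.091, 0.337)  # fraction lost I->III
    wu_decline_range: tuple[float, float] = (0.44, 0.761)
    nir_rise_range: tuple[float, float] = (0.035, 0.146)
    psa_base_range: tuple[float, float] = (1500.0, 2200.0)  # cm2 at stage I
    wu_base: float = 3.0  # ml/g/day at stage I
    psa_recovery_fraction: float = 0.6  # share of lost PSA regained by stage V
    wu_recovery_fraction: float = 0.6


@dataclass(frozen=True)
class CohortConfig:
    """Design of the synthetic experiment.

    Defaults reproduce the reference study's conditions: 35 NILs + 2
    parents, five imaging stages, pot-yield scale of ~7.5-14 g/plant,
    RDY spanning 0-0.73 with a cohort mean of 0.34, and a median
    cumulative pot-water loss of 1,840 g by day 11 triggering lifesaving
    irrigation on day 12.
    """

    n_nil: int = 35
    seed: int = 0
    stage_days: tuple[int, ...] = (0, 5, 10, 12, 15)
    anchors: TraitAnchors = field(default_factory=TraitAnchors)
    yp_range: tuple[float, float] = (7.5, 14.0)  # g/plant unstressed
    rdy_range: tuple[float, float] = (0.0, 0.73)  # mapped from tau (decreasing)
    #: NIL tau draw; with rdy_range (0, 0.73) the uniform lower bound 0.068
    #: puts the cohort-mean RDY at the observed 0.34
    tau_range: tuple[float, float] = (0.068, 1.0)
    rp_tau: float = 0.027  # recurrent parent: near the RDY-worst end (RDY ~ 0.71)
    dp_tau: float = 0.33  # donor parent: mid-high tolerance (RDY ~ 0.49)
    #: relative spread of decline magnitudes across tau (dimensionless)
    decline_spread: float = 0.8
    recovery_spread: float = 0.6
    noise_sd: dict = field(
        default_factory=lambda: {"PSA": 15.0, "WU": 0.08, "TR": 0.002, "NIR": 1.5, "yield": 0.5}
    )
    pot: PotGeometry = field(default_factory=PotGeometry)
    loss_target_g: float = 1840.0  # median cumulative ET at loss_target_day
    loss_target_day: int = 11
    irrigation_day: int = 12
    n_days: int = 15
    n_mock: int = 4  # mock pots per treatment
    evap_day_sd: float = 0.05  # shared day-to-day evaporation variability
    mock_noise_sd: float = 2.0  # per-mock-pot weighing/evaporation noise, g
    tillers_range: tuple[int, int] = (9, 14)

    def __post_init__(self):
        if self.n_nil < 1:
            raise ValueError("n_nil must be >= 1")
        days = self.stage_days
        if len(days) != 5 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("stage_days must be 5 strictly increasing day offsets")
        lo, hi = self.rdy_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("rdy_range must satisfy 0 <= rdy_min <= rdy_max <= 1")

    def rdy_of_tau(self, tau: float | np.ndarray) -> float | np.ndarray:
        """Expected relative yield drop: linear in tau, decreasing."""
        lo, hi = self.rdy_range
        return hi + (lo - hi) * np.asarray(tau, float)


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    """Independent deterministic substream per simulation stage."""
    digest = hashlib.sha256(f"{config.seed}:{stream}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def make_cohort(config: CohortConfig) -> list[Genotype]:
    """NILs plus the two parents, with deterministic latent tolerances."""
    rng = _rng(config, "cohort")
    taus = rng.uniform(*config.tau_range, size=config.n_nil)
    cohort = [Genotype(f"SYN-NIL-{i + 1:03d}", "NIL", float(t)) for i, t in enumerate(taus)]
    cohort.append(Genotype("SYN-RP", "RP", config.rp_tau))
    cohort.append(Genotype("SYN-DP", "DP", config.dp_tau))
    return cohort


def simulate_yields(cohort: list[Genotype], config: CohortConfig) -> pd.DataFrame:
    """Per-genotype (Yp, Ys): Ys = Yp * (1 - RDY(tau)) + noise, clamped."""
    if not cohort:
        raise ValueError("cohort is empty")
    rng = _rng(config, "yields")
    sd = config.noise_sd.get("yield", 0.0)
    rows = []
    for g in cohort:
        yp = float(rng.uniform(*config.yp_range))
        ys = yp * (1.0 - float(config.rdy_of_tau(g.tau)))
        if sd > 0:
            ys += float(rng.normal(0.0, sd))
        ys = float(np.clip(ys, 0.0, yp))
        rows.append({"genotype": g.id, "role": g.role, "tau": g.tau, "Yp": yp, "Ys": ys})
    return pd.DataFrame(rows)


def _stage_values(v1: float, v3: float, v5: float, days: tuple[int, ...]) -> np.ndarray:
    """Interpolate the five stage values from the I/III/V knots by day."""
    d = np.asarray(days, float)
    return np.interp(d, [d[0], d[2], d[4]], [v1, v3, v5])


def simulate_trajectories(cohort: list[Genotype], config: CohortConfig) -> pd.DataFrame:
    """Stage-wise PSA/WU/TR/NIR per genotype x treatment, long format.

    Stressed series decline from stage I to III and partially recover by
    stage V (NIR mirrors: rise then fall); unstressed series are flat
    except NIR, which drifts upward with maturity. Cohort means at the
    anchor stages match `config.anchors` up to noise and a small
    tau-covariance term (see the methods note).
    """
    rng = _rng(config, "trajectories")
    a = config.anchors
    taus = np.array([g.tau for g in cohort])
    tau_bar = taus.mean()
    c, c2 = config.decline_spread, config.recovery_spread

    mean_declines = {
        "PSA": 0.5 * (a.psa_decline_range[0] + a.psa_decline_range[1]),
        "WU": 0.5 * (a.wu_decline_range[0] + a.wu_decline_range[1]),
        "TR": 1.0 - a.tr_stressed[1] / a.tr_stressed[0],
        "NIR": (a.nir_stressed[1] - a.nir_stressed[0]) / a.nir_stressed[0],  # a rise
    }
    recovery_targets = {
        "PSA": a.psa_recovery_fraction,
        "WU": a.wu_recovery_fraction,
        "TR": (a.tr_stressed[2] - a.tr_stressed[1]) / (a.tr_stressed[0] - a.tr_stressed[1]),
        "NIR": (a.nir_stressed[1] - a.nir_stressed[2]) / (a.nir_stressed[1] - a.nir_stressed[0]),
    }
    #: decline grows with (1 - tau) for the damage traits, with tau for the
    #: water-saving traits; recovery speed always grows with tau
    damage_sign = {"PSA": -1.0, "NIR": -1.0, "WU": +1.0, "TR": +1.0}

    days = config.stage_days
    rows = []
    for g in cohort:
        x = g.tau - tau_bar
        bases = {
            "PSA": float(_rng(config, f"base:{g.id}").uniform(*a.psa_base_range)),
            "WU": a.wu_base,
            "TR": a.tr_stressed[0],
            "NIR": a.nir_stressed[0],
        }
        rho = {t: max(0.0, recovery_targets[t] * (1.0 + c2 * x)) for t in TRAITS}
        for trait in TRAITS:
            b = bases[trait]
            d = mean_declines[trait] * (1.0 + damage_sign[trait] * c * x)
            if trait == "NIR":
                v1, v3 = b, b * (1.0 + max(d, 0.0))
            else:
                v1, v3 = b, b * (1.0 - float(np.clip(d, 0.0, 0.95)))
            v5 = v3 + rho[trait] * (v1 - v3)
            stressed = _stage_values(v1, v3, v5, days)
            if trait == "NIR":
                u1, u5 = a.nir_unstressed
                unstressed = u1 + (u5 - u1) * (np.asarray(days, float) - days[0]) / (
                    days[-1] - days[0]
                )
            else:
                unstressed = np.full(5, b)
            sd = config.noise_sd.get(trait, 0.0)
            for series, treatment in ((stressed, "stressed"), (unstressed, "unstressed")):
                noisy = series + (rng.normal(0.0, sd, 5) if sd > 0 else 0.0)
                noisy = np.maximum(noisy, 0.0)
                for stage, value in zip(STAGES, noisy):
                    rows.append(
                        {
                            "genotype": g.id,
                            "role": g.role,
                            "treatment": treatment,
                            "stage": stage,
                            "trait": trait,
                            "value": float(value),
                        }
                    )
    return pd.DataFrame(rows)


def _daily_trait(
    traj: pd.DataFrame, genotype: str, trait: str, config: CohortConfig, treatment: str = "stressed"
) -> np.ndarray:
    """Interpolate a stage series onto integer days 0..n_days.

    For stressed pots, days between stage III and irrigation hold the
    stage-III (peak stress) value; recovery interpolation starts at the
    irrigation day. Unstressed series interpolate the stage days directly.
    """
    sub = traj[
        (traj["genotype"] == genotype)
        & (traj["treatment"] == treatment)
        & (traj["trait"] == trait)
    ].set_index("stage")["value"]
    v = [sub[s] for s in STAGES]
    d = list(config.stage_days)
    if treatment == "stressed":
        knot_days = [d[0], d[1], d[2], config.irrigation_day - 1, config.irrigation_day, d[3], d[4]]
        knot_vals = [v[0], v[1], v[2], v[2], v[2], v[3], v[4]]
    else:
        knot_days, knot_vals = d, v
    # de-duplicate in case irrigation day coincides with a stage day
    pairs = sorted(dict(zip(knot_days, knot_vals)).items())
    days = np.arange(config.n_days + 1, dtype=float)
    return np.interp(days, [p[0] for p in pairs], [p[1] for p in pairs])


def simulate_pot_weights(
    cohort: list[Genotype], traj: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Daily pot weights consistent with the simulated TR x PSA budget.

    Each stressed pot loses plant transpiration (TR * PSA, interpolated
    daily) plus a shared daily evaporation; mock pots lose evaporation
    only. The evaporation base is set so the cohort-median cumulative loss
    on `loss_target_day` equals `loss_target_g`, the depletion at which
    the soil reaches the irrigation-trigger moisture. Irrigation restores
    every stressed pot to saturation on `irrigation_day`; unstressed pots
    are topped up to saturation daily.
    """
    rng = _rng(config, "pots")
    days = np.arange(config.n_days + 1)
    t_daily = {}
    for treatment in ("stressed", "unstressed"):
        for g in cohort:
            tr = _daily_trait(traj, g.id, "TR", config, treatment)
            psa = _daily_trait(traj, g.id, "PSA", config, treatment)
            t_daily[g.id, treatment] = tr * psa  # g water / day
    median_t_sum = float(
        np.median(
            [
                t_daily[g.id, "stressed"][1 : config.loss_target_day + 1].sum()
                for g in cohort
            ]
        )
    )
    e_base = max(0.0, (config.loss_target_g - median_t_sum) / config.loss_target_day)
    evap_factors = {
        tr_name: 1.0 + rng.normal(0.0, config.evap_day_sd, len(days))
        for tr_name in ("stressed", "unstressed")
    }

    saturated = config.pot.saturated_weight_g
    rows = []

    def emit(pot, genotype, treatment, weights, irrigations):
        for d, w in zip(days, weights):
            rows.append(
                {
                    "pot": pot,
                    "genotype": genotype,
                    "treatment": treatment,
                    "day": int(d),
                    "weight": float(w),
                    "irrigation": float(irrigations.get(int(d), 0.0)),
                }
            )

    for treatment in ("stressed", "unstressed"):
        e_daily = e_base * evap_factors[treatment]
        # planted pots
        for g in cohort:
            losses = e_daily + t_daily[g.id, treatment]
            weights = [saturated]
            irrigations: dict[int, float] = {}
            for d in days[1:]:
                w = weights[-1] - losses[d]
                # stressed pots receive the single lifesaving irrigation;
                # unstressed pots are topped up to saturation every day
                if treatment == "unstressed" or d == config.irrigation_day:
                    irrigations[int(d)] = saturated - w
                    w = saturated
                weights.append(w)
            emit(f"{g.id}:{treatment}", g.id, treatment, weights, irrigations)
        # mock pots: evaporation only, with per-pot measurement noise
        for m in range(config.n_mock):
            noise = rng.normal(0.0, config.mock_noise_sd, len(days))
            weights = [saturated]
            irrigations = {}
            for d in days[1:]:
                w = weights[-1] - (e_daily[d] + noise[d])
                if treatment == "unstressed" or d == config.irrigation_day:
                    irrigations[int(d)] = saturated - w
                    w = saturated
                weights.append(w)
            emit(f"MOCK-{m + 1}:{treatment}", "MOCK", treatment, weights, irrigations)
    return pd.DataFrame(rows)


def simulate_tillers(cohort: list[Genotype], config: CohortConfig) -> pd.DataFrame:
    """Tiller counts per genotype (used for PSA-per-tiller)."""
    rng = _rng(config, "tillers")
    lo, hi = config.tillers_range
    return pd.DataFrame(
        {"genotype": [g.id for g in cohort], "tillers": rng.integers(lo, hi + 1, len(cohort))}
    )


def write_dataset(
    out_dir: str | Path,
    cohort: list[Genotype],
    yields: pd.DataFrame,
    traj: pd.DataFrame,
    pot_weights: pd.DataFrame,
    config: CohortConfig,
    images: dict[str, "object"] | None = None,
) -> dict:
    """Write CSV tables (+ optional PNGs) and a checksummed manifest."""
    import imageio.v3 as iio

    out = Path(out_dir)
    if not out.parent.exists():
        raise FileNotFoundError(f"parent of output directory does not exist: {out.parent}")
    out.mkdir(parents=True, exist_ok=True)

    genotypes = pd.DataFrame([asdict(g) for g in cohort])
    files = {
        "genotypes.csv": genotypes,
        "yields.csv": yields,
        "trajectories.csv": traj,
        "pot_weights.csv": pot_weights,
    }
    written: list[Path] = []
    for name, df in files.items():
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    if images:
        img_dir = out / "images"
        img_dir.mkdir(exist_ok=True)
        image_meta: dict = {}
        for key, image_set in images.items():
            for view, raster in image_set.rgb.items():
                p = img_dir / f"{key}_{view}_rgb.png"
                iio.imwrite(p, raster)
                written.append(p)
            for view, raster in image_set.nir.items():
                p = img_dir / f"{key}_{view}_nir.png"
                iio.imwrite(p, raster)
                written.append(p)
            image_meta[key] = {
                "px_per_cm": image_set.px_per_cm,
                "control_points_nir": image_set.control_points_nir.tolist(),
                "control_points_rgb": image_set.control_points_rgb.tolist(),
            }
        meta_path = img_dir / "image_meta.json"
        meta_path.write_text(json.dumps(image_meta, indent=2))
        written.append(meta_path)

    cfg_path = out / "config.json"
    cfg = asdict(config)
    cfg_path.write_text(json.dumps(cfg, indent=2, default=list))
    written.append(cfg_path)

    manifest = {
        "n_genotypes": len(cohort),
        "treatments": sorted(traj["treatment"].unique().tolist()),
        "seed": config.seed,
        "files": {
            str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
            for p in written
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
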