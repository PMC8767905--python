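"""Gravimetric water budget of potted plants.

Daily pot weighing turns each pot into a lysimeter: the day-over-day weight
drop (plus any irrigation added) is evapotranspiration ET; plant-free mock
pots lose only soil evaporation E, so whole-plant transpiration is
T = max(ET - E, 0). T normalized by projected shoot area gives the
transpiration rate TR (g/cm2/day) and, scaled by a biomass proxy, the
water use WU (ml/g/day; 1 g of water = 1 ml).

Soil moisture content is gravimetric (mass water per mass dry soil, w/w):
with a known tare and dry-soil mass, the remaining water in a pot follows
directly from its weight, and the lifesaving-irrigation trigger is the
first day SMC falls to the configured threshold (default 12 %, i.e. half
of the 25 % saturation of a flooded pot).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PotGeometry",
    "daily_et",
    "mock_evaporation",
    "transpiration",
    "transpiration_rate",
    "water_use",
    "gravimetric_smc",
    "smc_from_weight",
    "stress_trigger",
    "water_budget",
]


@dataclass(frozen=True)
class PotGeometry:
    """Mass composition of a saturated pot.

    tare_g: container + plant-independent hardware; dry_soil_g: oven-dry
    soil mass; water_at_saturation_g: water held at full saturation.
    Defaults give an 18,500 g saturated pot at 25 % w/w SMC.
    """

    tare_g: float = 1000.0
    dry_soil_g: float = 14000.0
    water_at_saturation_g: float = 3500.0

    @property
    def saturated_weight_g(self) -> float:
        return self.tare_g + self.dry_soil_g + self.water_at_saturation_g

    @property
    def smc_at_saturation(self) -> float:
        return gravimetric_smc(self.water_at_saturation_g, self.dry_soil_g)


def daily_et(weights: pd.Series, irrigation: dict[int, float] | None = None) -> pd.Series:
    """Evapotranspiration per day from a day-indexed weight series (g).

    ET on day d is W_{d-1} - W_d plus whatever irrigation was added on day
    d (added water masks the loss, so it must be credited back).
    """
    if len(weights) < 2:
        raise ValueError("need at least two days of weights")
    days = np.asarray(weights.index)
    if not np.all(np.diff(days) > 0):
        raise ValueError("day index must be strictly increasing")
    irrigation = irrigation or {}
    et = -weights.diff().dropna()
    for day, added in irrigation.items():
        if day in et.index:
            et.loc[day] += added
    return et


def mock_evaporation(mock_et: pd.DataFrame) -> pd.Series:
    """Daily evaporation E as the across-mock mean of daily ET.

    mock_et: one column per mock pot, day-indexed rows of daily ET.
    """
    if mock_et.shape[1] < 1:
        raise ValueError("at least one mock pot is required to estimate E")
    return mock_et.mean(axis=1)


def transpiration(et: float | np.ndarray, e: float | np.ndarray) -> float | np.ndarray:
    """T = max(ET - E, 0); clamped days are physically zero transpiration."""
    t = np.subtract(et, e)
    clamped = np.sum(np.asarray(t) < 0)
    if clamped:
        warnings.warn(f"clamped {int(clamped)} negative transpiration value(s) to 0")
    return np.maximum(t, 0.0) if np.ndim(t) else float(max(t, 0.0))


def transpiration_rate(t: float, psa_cm2: float) -> float:
    """TR = T / PSA in g/cm2 (per day when T is a daily total)."""
    if psa_cm2 <= 0:
        raise ValueError(f"PSA must be positive, got {psa_cm2}")
    return t / psa_cm2


def water_use(t_g_per_day: float, biomass_proxy_g: float) -> float:
    """WU in ml/g/day: daily transpired water over a biomass proxy.

    The biomass proxy is a modelling choice; a linear fresh-biomass
    calibration kappa * PSA (kappa default 0.2 g/cm2) or a harvested
    biomass both work — see the pipeline configuration.
    """
    if biomass_proxy_g <= 0:
        raise ValueError(f"biomass proxy must be positive, got {biomass_proxy_g}")
    return t_g_per_day / biomass_proxy_g


def gravimetric_smc(water_mass_g: float, dry_soil_mass_g: float) -> float:
    """Soil moisture content, % mass of water per mass of dry soil."""
    if dry_soil_mass_g <= 0:
        raise ValueError(f"dry soil mass must be positive, got {dry_soil_mass_g}")
    return 100.0 * water_mass_g / dry_soil_mass_g


def smc_from_weight(weight_g: float | np.ndarray, geometry: PotGeometry) -> float | np.ndarray:
    """SMC of a pot from its gross weight and mass composition."""
    water = np.asarray(weight_g, dtype=float) - geometry.tare_g - geometry.dry_soil_g
    smc = 100.0 * water / geometry.dry_soil_g
    return float(smc) if np.ndim(weight_g) == 0 else smc


def stress_trigger(smc: pd.Series, threshold_pct: float = 12.0) -> int | None:
    """First day on which SMC drops to/below the trigger threshold.

    Returns None when the series never reaches the threshold (e.g. a
    well-watered pot, or a threshold of 0 on any bounded drying series).
    """
    if threshold_pct <= 0:
        return None
    hit = smc[smc <= threshold_pct]
    return int(hit.index[0]) if len(hit) else None


def water_budget(
    pot_weights: pd.DataFrame,
    geometry: PotGeometry | None = None,
    trigger_threshold_pct: float = 12.0,
) -> pd.DataFrame:
    """Per-pot, per-day ET/E/T/SMC table from a long pot-weight table.

    pot_weights columns: ``pot``, ``genotype`` (``MOCK`` for plant-free
    pots), ``treatment``, ``day``, ``weight``, ``irrigation`` (g added on
    that day, 0 if none).

    E is estimated per treatment and day from that treatment's mock pots;
    treatments without mocks raise, since T would be unidentifiable.
    """
    geometry = geometry or PotGeometry()
    required = {"pot", "genotype", "treatment", "day", "weight"}
    if not required.issubset(pot_weights.columns):
        raise ValueError(f"pot weight table needs columns {sorted(required)}")
    out = []
    for treatment, group in pot_weights.groupby("treatment", sort=False):
        per_pot_et = {}
        for pot, rows in group.groupby("pot", sort=False):
            rows = rows.sort_values("day")
            weights = rows.set_index("day")["weight"]
            irrig = {}
            if "irrigation" in rows.columns:
                irrig = {
                    int(d): float(a)
                    for d, a in zip(rows["day"], rows["irrigation"].fillna(0.0))
                    if a > 0
                }
            per_pot_et[pot] = daily_et(weights, irrig)
        is_mock = group.groupby("pot")["genotype"].first() == "MOCK"
        mock_pots = is_mock[is_mock].index
        if len(mock_pots) == 0:
            raise ValueError(f"treatment {treatment!r} has no mock pots; E unidentifiable")
        e_daily = mock_evaporation(pd.DataFrame({p: per_pot_et[p] for p in mock_pots}))
        for pot, et in per_pot_et.items():
            rows = group[group["pot"] == pot].sort_values("day")
            weights = rows.set_index("day")["weight"]
            e_aligned = e_daily.reindex(et.index)
            t = np.maximum(et - e_aligned, 0.0)
            if is_mock[pot]:
                t = pd.Series(0.0, index=et.index)
            smc = smc_from_weight(weights.loc[et.index].to_numpy(), geometry)
            cum = et.cumsum().to_numpy()  # total water lost via ET, irrigation-independent
            out.append(
                pd.DataFrame(
                    {
                        "pot": pot,
                        "genotype": rows["genotype"].iloc[0],
                        "treatment": treatment,
                        "day": et.index,
                        "ET": et.to_numpy(),
                        "E": e_aligned.to_numpy(),
                        "T": np.asarray(t),
                        "SMC": smc,
                        "cumulative_loss": cum,
                    }
                )
            )
    budget = pd.concat(out, ignore_index=True)
    triggers = {
        pot: stress_trigger(g.set_index("day")["SMC"], trigger_threshold_pct)
        for pot, g in budget.groupby("pot")
    }
    budget["trigger_day"] = budget["pot"].map(triggers).astype("float")
    return budget
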