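"""Food, feed and energy-supply demand model.

Per-capita meat and milk consumption follows income-driven growth curves
whose year-2050 endpoints interpolate, piecewise linearly, the printed
(parameter setting -> 2050 outcome) anchors of the model's uncertainty
table; the 2000 baseline is the group average (80/51/22 kg meat and
200/80/40 kg milk for groups 1/3/4). A global limit parameter ``consL``
caps meat at ``122.5 + consL`` and milk at ``240 + consL`` kg cap-1
yr-1. Countries with a baseline food-energy supply below 2200 kcal
cap-1 d-1 can additionally raise per-capita cereal consumption
(``cerealCon``). Cereal feed demand couples meat production back into
cereal demand through a feed conversion ratio (improving with
``fcr_improvement``) and a feed share of meat production (growing with
``feed_ratio_cap``).

All "(1/time)" effects accrue linearly as ``param * (year - 2000) / 100``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DemandConfig

#: 2050 per-capita consumption anchors (kg yr-1): for each (commodity,
#: group), parameter settings (min, trend, max) and resulting outcomes.
CONSUMPTION_ANCHORS: dict[tuple[str, int], tuple[tuple[float, ...], tuple[float, ...]]] = {
    ("meat", 1): ((-50.0, -30.0, 50.0), (70.0, 82.0, 121.0)),
    ("milk", 1): ((-200.0, -50.0, 50.0), (198.0, 268.0, 327.0)),
    ("meat", 3): ((0.0, 45.0, 60.0), (36.0, 83.0, 100.0)),
    ("milk", 3): ((0.0, 45.0, 90.0), (108.0, 162.0, 213.0)),
    ("meat", 4): ((5.0, 15.0, 43.0), (20.0, 40.0, 90.0)),
    ("milk", 4): ((20.0, 45.0, 70.0), (61.0, 109.0, 157.0)),
}


@dataclass(frozen=True)
class ConsumptionParams:
    """Group consumption parameters plus the global limit and cereal boost."""

    meat1: float
    milk1: float
    meat3: float
    milk3: float
    meat4: float
    milk4: float
    consL: float
    cerealCon: float

    def __post_init__(self) -> None:
        for (commodity, g), (thetas, _) in CONSUMPTION_ANCHORS.items():
            v = getattr(self, f"{commodity}{g}")
            if not thetas[0] <= v <= thetas[-1]:
                raise ValueError(f"{commodity}{g}={v} outside [{thetas[0]}, {thetas[-1]}]")
        if not -60.0 <= self.consL <= 20.0:
            raise ValueError("consL outside [-60, 20]")
        if not 0.0 <= self.cerealCon <= 0.4:
            raise ValueError("cerealCon outside [0, 0.4]")

    def theta(self, commodity: str, group: int) -> float:
        return getattr(self, f"{commodity}{group}")


@dataclass(frozen=True)
class FeedParams:
    """Feed conversion and feed-share settings."""

    fcr_improvement: float  # (1/time) efficiency gain
    feed_ratio_cap: float  # (1/time) growth of the fed share of meat
    fcr_2000: float = 10.5  # kg cereal-equivalent feed per kg meat
    feed_share_2000: float = 0.25  # share of meat produced with cereal feed
    cap_gain: float = 1.0  # converts feed_ratio_cap accrual into share points

    def __post_init__(self) -> None:
        if not 0.0 <= self.fcr_improvement <= 0.2:
            raise ValueError("fcr_improvement outside [0, 0.2]")
        if not 0.0 <= self.feed_ratio_cap <= 0.2:
            raise ValueError("feed_ratio_cap outside [0, 0.2]")
        if self.fcr_2000 <= 0 or not 0.0 < self.feed_share_2000 < 1.0:
            raise ValueError("invalid feed baseline")

    def fcr(self, year: float) -> float:
        """Feed conversion ratio in ``year`` (kg feed per kg meat)."""
        return self.fcr_2000 * (1.0 - self.fcr_improvement * (year - 2000.0) / 100.0)

    def feed_share(self, year: float) -> float:
        """Share of meat production using cereal feed in ``year``."""
        accrual = self.feed_ratio_cap * (year - 2000.0) / 100.0 * self.cap_gain
        return min(1.0, self.feed_share_2000 + accrual)


@dataclass(frozen=True)
class EnergyDensities:
    """Energy content of the three tracked commodities (kcal kg-1)."""

    cereal_kcal_per_kg: float = 3000.0
    meat_kcal_per_kg: float = 1900.0
    milk_kcal_per_kg: float = 600.0

    def __post_init__(self) -> None:
        if min(self.cereal_kcal_per_kg, self.meat_kcal_per_kg, self.milk_kcal_per_kg) <= 0:
            raise ValueError("energy densities must be positive")


def consumption_2050(commodity: str, group: int, theta: float) -> float:
    """Year-2050 per-capita consumption (kg yr-1) at reference income.

    Piecewise-linear interpolation of the printed (setting -> outcome)
    anchors; exact at the min, trend and max settings by construction.
    """
    key = (commodity, group)
    if key not in CONSUMPTION_ANCHORS:
        raise ValueError(f"no anchors for {commodity!r} group {group}")
    thetas, outcomes = CONSUMPTION_ANCHORS[key]
    if not thetas[0] <= theta <= thetas[-1]:
        raise ValueError(f"theta={theta} outside [{thetas[0]}, {thetas[-1]}]")
    return float(np.interp(theta, thetas, outcomes))


def percap_animal_consumption(commodity: str, group: int, theta: float,
                              year: float, income_index: float = 1.0,
                              config: DemandConfig | None = None) -> float:
    """Per-capita meat or milk consumption (kg yr-1) in ``year``.

    Linear ramp from the group's 2000 baseline to the 2050 anchor value,
    with the growth increment scaled by ``income_index`` (the country's
    income relative to the reference growth path; 1 means on-reference).
    Monotone non-decreasing in ``theta``.
    """
    if not 2000.0 <= year <= 2050.0:
        raise ValueError("year outside the 2000-2050 horizon")
    if income_index < 0:
        raise ValueError("income_index must be non-negative")
    cfg = config or DemandConfig()
    base = {"meat": cfg.meat_baseline, "milk": cfg.milk_baseline}[commodity][group]
    target = consumption_2050(commodity, group, theta)
    ramp = (year - 2000.0) / 50.0
    return base + (target - base) * ramp * income_index


def apply_consumption_limit(meat_pc, milk_pc, consL: float,
                            config: DemandConfig | None = None):
    """Apply the global animal-product consumption limit.

    Meat is capped at ``122.5 + consL`` and milk at ``240 + consL`` kg
    cap-1 yr-1, so the trend setting (consL=0) caps meat at 122.5 kg and
    leaves milk unaffected at simulated levels, while consL=-60 gives the
    62.5 kg meat / 180 kg milk caps.
    """
    if not -60.0 <= consL <= 20.0:
        raise ValueError("consL outside [-60, 20]")
    cfg = config or DemandConfig()
    return (np.minimum(meat_pc, cfg.meat_cap_base + consL),
            np.minimum(milk_pc, cfg.milk_cap_base + consL))


def cereal_boost_factor(kcal_2000, cerealCon: float, year: float,
                        threshold: float = 2200.0):
    """Multiplier on per-capita food-cereal demand for low-supply countries.

    Countries with a baseline supply below ``threshold`` kcal cap-1 d-1
    accrue ``1 + cerealCon * (year - 2000)/100``; others are unaffected.
    """
    if not 0.0 <= cerealCon <= 0.4:
        raise ValueError("cerealCon outside [0, 0.4]")
    boost = 1.0 + cerealCon * (year - 2000.0) / 100.0
    return np.where(np.asarray(kcal_2000) < threshold, boost, 1.0)


def feed_demand(meat_production, year: float, feed: FeedParams):
    """Cereal feed demand (Mt) implied by ``meat_production`` (Mt)."""
    meat_production = np.asarray(meat_production, dtype=float)
    if (meat_production < 0).any():
        raise ValueError("meat production must be non-negative")
    return meat_production * feed.feed_share(year) * feed.fcr(year)


def food_energy_supply(cereal_pc, meat_pc, milk_pc,
                       densities: EnergyDensities | None = None,
                       other_supply_kcal=0.0):
    """Daily food-energy supply (kcal cap-1 d-1).

    ``other_supply_kcal`` is the country's fixed residual from all foods
    outside the three tracked commodities; it is calibrated at baseline so
    that the year-2000 identity returns the observed supply exactly.
    """
    d = densities or EnergyDensities()
    cereal_pc, meat_pc, milk_pc = (np.asarray(x, dtype=float) for x in (cereal_pc, meat_pc, milk_pc))
    if (cereal_pc < 0).any() or (meat_pc < 0).any() or (milk_pc < 0).any():
        raise ValueError("consumption must be non-negative")
    kcal = (cereal_pc * d.cereal_kcal_per_kg + meat_pc * d.meat_kcal_per_kg
            + milk_pc * d.milk_kcal_per_kg) / 365.0
    return kcal + other_supply_kcal


def income_index(gdp_pc_path, t: int, ref_growth: float = 0.02,
                 clip: tuple[float, float] = (0.6, 1.4)):
    """Country income at step ``t`` relative to the reference growth path.

    The ratio of realised income growth since 2000 to growth at the
    reference rate, clipped to a plausible modulation band.
    """
    gdp_pc_path = np.asarray(gdp_pc_path, dtype=float)
    ratio = (gdp_pc_path[..., t] / gdp_pc_path[..., 0]) / (1.0 + ref_growth) ** t
    return np.clip(ratio, *clip)
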