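"""The three normative targets and the unit conversions they use.

* Food supply: every country's average daily food-energy supply in 2050
  must reach at least 2635 kcal cap-1 d-1 (a 2350 kcal dietary
  requirement grossed up for ~12% household waste; the printed 2635 is
  used verbatim).
* Cropland planetary boundary: global cropland in 2050 must not exceed
  15% of the 13400 Mha ice-free land surface, i.e. 2010 Mha.
* Bioenergy mitigation: first-generation bioenergy crops must deliver
  the stringent-mitigation pathway's 2050 first-generation energy
  (125 EJ x 7% = 8.75 EJ, printed as 9 EJ) with no unmet bioenergy crop
  demand.

Threshold comparisons are inclusive. The ``closeness`` score sums the
three relative shortfalls, so it is zero exactly when all targets are
met and continuous across each threshold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .supply_trade import WorldState

TOE_TO_GJ = 41.868  # tonnes of oil equivalent -> GJ, definitional


@dataclass(frozen=True)
class TargetSpec:
    """Constants defining the three normative targets."""

    kcal_threshold: float = 2635.0  # kcal cap-1 d-1, per-country average
    dietary_requirement: float = 2350.0  # kcal cap-1 d-1
    household_waste: float = 0.12  # fraction of supply wasted at home
    boundary_share: float = 0.15  # of ice-free land
    ice_free_land: float = 13400.0  # Mha
    cropland_boundary: float = 2010.0  # Mha, = boundary_share * ice_free_land
    bioenergy_target: float = 8.75  # EJ of first-generation bioenergy by 2050
    evaluation_year: int = 2050

    def __post_init__(self) -> None:
        if min(self.kcal_threshold, self.dietary_requirement, self.boundary_share,
               self.ice_free_land, self.cropland_boundary, self.bioenergy_target) <= 0:
            raise ValueError("target constants must be positive")
        expected = self.boundary_share * self.ice_free_land
        if abs(self.cropland_boundary - expected) > 1e-6 * expected:
            raise ValueError(
                f"cropland_boundary {self.cropland_boundary} != "
                f"boundary_share*ice_free_land = {expected}")


@dataclass(frozen=True)
class TargetOutcome:
    """Pass/fail plus signed margins for one simulation run."""

    food_met: bool
    cropland_met: bool
    bioenergy_met: bool
    food_margin: float  # kcal cap-1 d-1, min country supply - threshold
    cropland_margin: float  # Mha, boundary - global cropland
    bioenergy_margin: float  # EJ, delivered - target
    closeness: float  # >= 0; zero iff all three targets met

    @property
    def n_met(self) -> int:
        return int(self.food_met) + int(self.cropland_met) + int(self.bioenergy_met)

    def as_dict(self) -> dict:
        return {
            "food_met": self.food_met, "cropland_met": self.cropland_met,
            "bioenergy_met": self.bioenergy_met, "food_margin": self.food_margin,
            "cropland_margin": self.cropland_margin,
            "bioenergy_margin": self.bioenergy_margin, "closeness": self.closeness,
        }


def cropland_boundary_mha(boundary_share: float, ice_free_land: float) -> float:
    """Cropland planetary boundary (Mha) from its share of ice-free land."""
    if not 0.0 < boundary_share < 1.0:
        raise ValueError("boundary_share must be in (0, 1)")
    if ice_free_land < 0:
        raise ValueError("ice_free_land must be non-negative")
    return boundary_share * ice_free_land


def cropland_share_pct(cropland: float, ice_free_land: float) -> float:
    """Cropland as a percentage of ice-free land, to one decimal."""
    if ice_free_land <= 0:
        raise ValueError("ice_free_land must be positive")
    return round(100.0 * cropland / ice_free_land, 1)


def mtoe_to_ej(mtoe: float) -> float:
    """Million tonnes of oil equivalent to EJ (1 toe = 41.868 GJ)."""
    if mtoe < 0:
        raise ValueError("mtoe must be non-negative")
    return mtoe * TOE_TO_GJ / 1000.0


def first_gen_target_ej(total_2050: float, share: float) -> float:
    """First-generation bioenergy (EJ) from total bioenergy and its share."""
    if not 0.0 <= share <= 1.0:
        raise ValueError("share must be in [0, 1]")
    return total_2050 * share


def cagr_pct(start: float, end: float, years: float) -> float:
    """Compound annual growth rate in percent per year."""
    if start <= 0:
        raise ValueError("start must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    return 100.0 * ((end / start) ** (1.0 / years) - 1.0)


def closeness_score(min_kcal: float, global_cropland: float, delivered_ej: float,
                    spec: TargetSpec) -> float:
    """Sum of normalised target shortfalls; zero iff all targets met."""
    food_short = max(0.0, (spec.kcal_threshold - min_kcal) / spec.kcal_threshold)
    land_short = max(0.0, (global_cropland - spec.cropland_boundary) / spec.cropland_boundary)
    bio_short = max(0.0, (spec.bioenergy_target - delivered_ej) / spec.bioenergy_target)
    return food_short + land_short + bio_short


def evaluate_targets(final_state: WorldState, spec: TargetSpec | None = None) -> TargetOutcome:
    """Evaluate the three normative targets on the 2050 world state.

    Food: every country's supply >= the threshold. Cropland: global
    cropland <= the boundary. Bioenergy: delivered first-generation
    energy >= the target and zero unmet bioenergy crop demand.
    """
    spec = spec or TargetSpec()
    if final_state.year != spec.evaluation_year:
        raise ValueError(
            f"targets are evaluated at {spec.evaluation_year}, got {final_state.year}")
    if final_state.kcal is None:
        raise ValueError("final state lacks per-country kcal supply")
    min_kcal = float(np.min(final_state.kcal))
    cropland = float(final_state.global_cropland)
    delivered = float(final_state.first_gen_delivered_ej)

    food_margin = min_kcal - spec.kcal_threshold
    cropland_margin = spec.cropland_boundary - cropland
    bio_margin = delivered - spec.bioenergy_target
    bio_met = bio_margin >= 0 and final_state.unmet_bioenergy_mt <= 1e-9
    return TargetOutcome(
        food_met=food_margin >= 0,
        cropland_met=cropland_margin >= 0,
        bioenergy_met=bool(bio_met),
        food_margin=food_margin,
        cropland_margin=cropland_margin,
        bioenergy_margin=bio_margin,
        closeness=closeness_score(min_kcal, cropland, delivered, spec),
    )
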