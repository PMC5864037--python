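"""Supply side: yield-gap closure, degradation, bioenergy land, trade.

Yields converge toward an exogenous potential at a rate driven by
technological development (``technology``) and income-dependent
investment (``investments``): each year the relative yield gap
``g = 1 - actual/potential`` shrinks by the factor
``1 - kappa * (technology + investments * min(1, growth/ref)) / 100``,
where ``kappa`` is a single global scale calibrated so the all-trend run
reproduces the printed 2050 global mean yield (5.13 t ha-1).

Cropland degradation removes ``croplandDeg * (year-2000)/100`` of gross
production. First-generation bioenergy crop demand follows a linear path
to its 2050 endpoint (total bioenergy x first-generation share).

Trade assumes a single global market: each country first covers its own
demand up to its land ceiling ``suitable * (1 - residualNV/100)``; the
remaining global deficit is covered by exporters in descending order of
effective yield (a land-minimising cost proxy), expanding cropland up to
their ceilings. Shortfall that no country can cover is recorded as unmet
demand, and importing countries are then served pro rata.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SupplyParams:
    """Sampled supply-side parameters plus the calibrated closure scale."""

    technology: float  # (1/time) yield growth from technological change
    investments: float  # (1/time) yield growth from income growth
    residualNV: float  # % of potential arable land reserved for nature
    croplandDeg: float  # (1/time) production share lost to degradation
    kappa: float = 1.0  # calibrated closure-rate scale

    def __post_init__(self) -> None:
        if not 0.0 <= self.technology <= 2.0:
            raise ValueError("technology outside [0, 2]")
        if not 0.0 <= self.investments <= 1.7:
            raise ValueError("investments outside [0, 1.7]")
        if not 1.0 <= self.residualNV <= 20.0:
            raise ValueError("residualNV outside [1, 20]")
        if not 0.04 <= self.croplandDeg <= 0.1:
            raise ValueError("croplandDeg outside [0.04, 0.1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class BioenergySettings:
    """Exogenous first-generation bioenergy crop demand path."""

    total_bioenergy_2050: float  # EJ, all bioenergy
    first_gen_share_2050: float  # fraction from first-generation crops
    crop_energy_content: float = 8.0  # GJ per tonne of energy crop
    path_shape: str = "linear"  # demand path from 0 in 2000 to the endpoint

    def __post_init__(self) -> None:
        if self.total_bioenergy_2050 <= 0:
            raise ValueError("total_bioenergy_2050 must be positive")
        if not 0.0 <= self.first_gen_share_2050 <= 1.0:
            raise ValueError("first_gen_share_2050 outside [0, 1]")
        if self.crop_energy_content <= 0:
            raise ValueError("crop_energy_content must be positive")
        if self.path_shape != "linear":
            raise ValueError("only the linear demand path is implemented")


@dataclass
class WorldState:
    """Per-country state and global aggregates for one simulated year."""

    year: int
    cropland: np.ndarray  # Mha (food + bioenergy land)
    yield_t_ha: np.ndarray  # t ha-1 (actual)
    production: np.ndarray  # Mt, gross
    demand: np.ndarray  # Mt (food + feed + other crop demand)
    imports: np.ndarray  # Mt
    exports: np.ndarray  # Mt
    kcal: np.ndarray | None = None  # kcal cap-1 d-1
    global_cropland: float = 0.0  # Mha
    global_mean_yield: float = 0.0  # t ha-1, net production / cropland
    unmet_demand: float = 0.0  # Mt
    first_gen_delivered_ej: float = 0.0
    unmet_bioenergy_mt: float = 0.0
    extras: dict = field(default_factory=dict)


def yield_gap(actual, potential):
    """Relative yield gap ``1 - actual/potential`` in [0, 1]."""
    actual = np.asarray(actual, dtype=float)
    potential = np.asarray(potential, dtype=float)
    if (potential <= 0).any():
        raise ValueError("potential yield must be positive")
    if (actual <= 0).any() or (actual > potential * (1 + 1e-12)).any():
        raise ValueError("actual yield must be in (0, potential]")
    return 1.0 - actual / potential


def closure_rate(params: SupplyParams, income_growth) -> np.ndarray:
    """Annual fractional shrinkage of the yield gap."""
    invest_factor = np.minimum(1.0, np.asarray(income_growth, dtype=float) / _REF_GROWTH)
    return params.kappa * (params.technology + params.investments * invest_factor) / 100.0


_REF_GROWTH = 0.02  # reference income growth rate for the investment effect


def update_yield(actual, potential, params: SupplyParams, income_growth,
                 potential_next=None):
    """Advance actual yield one year by shrinking the relative gap.

    The gap shrinks by ``1 - closure_rate``; the new yield is evaluated
    against ``potential_next`` (defaults to ``potential``), so that with
    technology = investments = 0 the yield simply tracks the potential's
    change at a constant gap ratio. Never exceeds the potential.
    """
    g = yield_gap(actual, potential)
    g = g * (1.0 - closure_rate(params, income_growth))
    p_next = potential if potential_next is None else np.asarray(potential_next, dtype=float)
    return p_next * (1.0 - g)


def degradation_loss(croplandDeg: float, year: float) -> float:
    """Fraction of gross production lost to cropland degradation."""
    if year < 2000:
        raise ValueError("year must be >= 2000")
    return croplandDeg * (year - 2000.0) / 100.0


def land_ceiling(suitable_land, residualNV: float):
    """Maximum cropland given the natural-vegetation reserve (Mha)."""
    return np.asarray(suitable_land, dtype=float) * (1.0 - residualNV / 100.0)


def bioenergy_crop_demand(year: float, settings: BioenergySettings) -> tuple[float, float]:
    """First-generation bioenergy demand in ``year``: (energy EJ, crop Mt).

    Energy demand rises linearly from zero in 2000 to
    ``total_bioenergy_2050 * first_gen_share_2050`` EJ in 2050; crop
    demand converts EJ to Mt through the crop energy content
    (EJ -> 1e3 PJ; PJ / (GJ t-1) -> Mt).
    """
    if not 2000.0 <= year <= 2050.0:
        raise ValueError("year outside the 2000-2050 horizon")
    endpoint = settings.total_bioenergy_2050 * settings.first_gen_share_2050
    energy = endpoint * (year - 2000.0) / 50.0
    crop = energy * 1000.0 / settings.crop_energy_content
    return energy, crop


@dataclass
class TradeAllocation:
    """Result of one year's market allocation."""

    cropland: np.ndarray  # Mha
    production: np.ndarray  # Mt gross
    net_supply: np.ndarray  # Mt after degradation loss
    imports: np.ndarray  # Mt
    exports: np.ndarray  # Mt
    served: np.ndarray  # Mt of demand actually met per country
    unmet: float  # Mt of global demand left unserved


def allocate_land_and_trade(demand, yield_t_ha, ceiling, loss: float = 0.0) -> TradeAllocation:
    """Allocate cropland and trade flows for one year.

    Deterministic: the export order is descending effective yield with
    ties broken by country position (ascending). Cropland contracts
    freely where demand falls; expansion stops at each country's ceiling.
    """
    demand = np.asarray(demand, dtype=float)
    y = np.asarray(yield_t_ha, dtype=float)
    ceiling = np.asarray(ceiling, dtype=float)
    if (demand < 0).any():
        raise ValueError("demand must be non-negative")
    if (y <= 0).any() or (ceiling < 0).any():
        raise ValueError("yields must be positive and ceilings non-negative")
    if not 0.0 <= loss < 1.0:
        raise ValueError("loss must be in [0, 1)")

    eff = y * (1.0 - loss)  # net tonnes per hectare
    land_dom = np.minimum(demand / eff, ceiling)
    net_dom = land_dom * eff
    deficit = np.maximum(demand - net_dom, 0.0)
    total_deficit = float(deficit.sum())

    expansion = np.zeros_like(demand)
    remaining = total_deficit
    if remaining > 0:
        order = np.argsort(-eff, kind="stable")
        headroom = ceiling - land_dom
        for i in order:
            if remaining <= 1e-15:
                break
            take = min(headroom[i], remaining / eff[i])
            if take > 0:
                expansion[i] = take
                remaining -= take * eff[i]
    unmet = max(remaining, 0.0)

    cropland = land_dom + expansion
    net = cropland * eff
    fill = 1.0 if total_deficit <= 0 else (total_deficit - unmet) / total_deficit
    imports = deficit * fill
    exports = expansion * eff
    served = demand - deficit + imports
    production = cropland * y
    return TradeAllocation(cropland=cropland, production=production, net_supply=net,
                           imports=imports, exports=exports, served=served, unmet=unmet)


def allocate_bioenergy(crop_demand: float, yield_t_ha, ceiling, cropland,
                       loss: float = 0.0) -> tuple[np.ndarray, float]:
    """Allocate bioenergy crop land on the capacity left after food.

    Food demand has market priority; bioenergy crops occupy remaining
    headroom in descending effective-yield order. Returns the per-country
    bioenergy land (Mha) and the unmet crop demand (Mt).
    """
    if crop_demand < 0:
        raise ValueError("crop demand must be non-negative")
    y = np.asarray(yield_t_ha, dtype=float)
    eff = y * (1.0 - loss)
    headroom = np.maximum(np.asarray(ceiling, dtype=float) - np.asarray(cropland, dtype=float), 0.0)
    bio_land = np.zeros_like(eff)
    remaining = float(crop_demand)
    order = np.argsort(-eff, kind="stable")
    for i in order:
        if remaining <= 1e-15:
            break
        take = min(headroom[i], remaining / eff[i])
        if take > 0:
            bio_land[i] = take
            remaining -= take * eff[i]
    return bio_land, max(remaining, 0.0)
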