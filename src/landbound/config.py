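"""Configuration objects and YAML loading.

Every tunable constant of the pipeline lives in one of the dataclasses
below; a YAML file with sections ``world:``, ``demand:``, ``supply:``,
``targets:`` and ``design:`` overrides individual fields.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

YEAR_START = 2000
YEAR_END = 2050
N_YEARS = YEAR_END - YEAR_START + 1


@dataclass(frozen=True)
class GroupThresholds:
    """Income / meat cut-offs for consumption-group assignment."""

    gdp_high: float = 12000.0  # USD per capita
    gdp_low: float = 3000.0
    meat_high: float = 65.0  # kg per capita per year
    meat_low: float = 35.0


@dataclass(frozen=True)
class WorldConfig:
    """Settings of the synthetic world generator.

    Group shares, baseline consumption/income/yield distributions and
    SSP2-like growth ranges. Ranges are (low, high) of uniform draws;
    keys 1, 3, 4 are the consumption groups (there is no group 2 in the
    model's group labelling).
    """

    n_countries: int = 150
    ice_free_land: float = 13400.0  # Mha
    cropland_share_2000: float = 0.12  # of ice-free land
    world_pop_2000: float = 6100.0  # millions
    low_supply_fraction: float = 0.2  # expected share of countries < 2200 kcal
    low_supply_kcal: float = 2200.0

    group_shares: dict = field(default_factory=lambda: {1: 0.25, 3: 0.45, 4: 0.30})
    thresholds: GroupThresholds = field(default_factory=GroupThresholds)

    # baseline daily food-energy supply ranges (kcal/cap/day); the group-4
    # upper bound is stretched at generation time so the expected share of
    # countries below `low_supply_kcal` matches `low_supply_fraction`
    kcal_range: dict = field(
        default_factory=lambda: {1: (3100.0, 3600.0), 3: (2550.0, 3250.0), 4: (1950.0, 2450.0)}
    )
    # baseline per-capita meat / milk consumption (kg/yr)
    meat_range: dict = field(
        default_factory=lambda: {1: (66.0, 105.0), 3: (36.0, 64.0), 4: (12.0, 34.0)}
    )
    milk_range: dict = field(
        default_factory=lambda: {1: (150.0, 260.0), 3: (50.0, 120.0), 4: (20.0, 70.0)}
    )
    # baseline GDP per capita (USD) and annual growth-rate ranges
    gdp_range: dict = field(
        default_factory=lambda: {1: (15000.0, 45000.0), 3: (3500.0, 11000.0), 4: (500.0, 2800.0)}
    )
    gdp_growth_range: dict = field(
        default_factory=lambda: {1: (0.010, 0.025), 3: (0.020, 0.035), 4: (0.025, 0.040)}
    )
    # chosen so expected world population reaches ~9.1 billion by 2050
    pop_growth_range: dict = field(
        default_factory=lambda: {1: (0.000, 0.006), 3: (0.004, 0.010), 4: (0.009, 0.017)}
    )
    # baseline actual yield (t/ha) and baseline yield gap ranges
    yield_range: dict = field(
        default_factory=lambda: {1: (4.0, 7.0), 3: (2.0, 5.0), 4: (1.0, 2.5)}
    )
    yield_gap_range: dict = field(
        default_factory=lambda: {1: (0.30, 0.55), 3: (0.40, 0.75), 4: (0.60, 0.90)}
    )
    # energy share of the fixed "other foods" residual in baseline supply
    other_supply_share_range: tuple = (0.15, 0.30)
    # non-cereal crop demand per capita (kg cereal-equivalent/yr), before
    # the closed-form global rescaling that pins baseline cropland
    other_crop_pc_range: tuple = (400.0, 700.0)
    # suitable land as a multiple of baseline cropland; kept tight so that
    # global capacity genuinely constrains high-demand futures
    suitable_multiple_range: tuple = (1.2, 2.5)
    # potential-yield trajectory: linear growth to 2050 and the quadratic
    # late-century climate penalty of the higher-warming variant
    potential_growth_2050: float = 0.30
    climate_penalty_2050: float = 0.08
    # global mean yield (production / cropland) calibration anchor at 2000
    global_yield_2000: float = 3.1

    def __post_init__(self) -> None:
        if self.n_countries < 3:
            raise ValueError("n_countries must be >= 3")
        if self.ice_free_land <= 0 or self.world_pop_2000 <= 0:
            raise ValueError("land area and population must be positive")
        if not 0 < self.cropland_share_2000 < 1:
            raise ValueError("cropland_share_2000 must be in (0, 1)")
        if abs(sum(self.group_shares.values()) - 1.0) > 1e-9:
            raise ValueError("group_shares must sum to 1")


@dataclass(frozen=True)
class DemandConfig:
    """Demand-side constants: energy densities, group baselines, feed."""

    # energy densities (kcal per kg)
    cereal_kcal_per_kg: float = 3000.0
    meat_kcal_per_kg: float = 1900.0
    milk_kcal_per_kg: float = 600.0
    # group baseline per-capita consumption in 2000 (kg/yr)
    meat_baseline: dict = field(default_factory=lambda: {1: 80.0, 3: 51.0, 4: 22.0})
    milk_baseline: dict = field(default_factory=lambda: {1: 200.0, 3: 80.0, 4: 40.0})
    # animal-product cap constants: cap = constant + consL
    meat_cap_base: float = 122.5
    milk_cap_base: float = 240.0
    # feed model: cereal-equivalent feed per kg meat and the share of meat
    # produced with cereal feed
    fcr_2000: float = 10.5
    feed_share_2000: float = 0.25
    feed_cap_gain: float = 1.0
    # income response: index relative to a reference growth path
    ref_income_growth: float = 0.02
    income_index_clip: tuple = (0.6, 1.4)
    # income elasticity of non-cereal crop demand
    other_income_elasticity: float = 0.25
    low_supply_kcal: float = 2200.0

    def __post_init__(self) -> None:
        for d in (self.cereal_kcal_per_kg, self.meat_kcal_per_kg, self.milk_kcal_per_kg):
            if d <= 0:
                raise ValueError("energy densities must be positive")
        if self.fcr_2000 <= 0 or not 0 < self.feed_share_2000 < 1:
            raise ValueError("invalid feed baseline")


@dataclass(frozen=True)
class SupplyConfig:
    """Supply-side constants: yield-gap closure and bioenergy conversion."""

    ref_income_growth: float = 0.02
    kappa: float | None = None  # closure-rate scale; calibrated if None
    yield_anchor_2050: float = 5.13  # t/ha, trend-run calibration target
    crop_energy_content: float = 8.0  # GJ per tonne of first-gen energy crop

    def __post_init__(self) -> None:
        if self.crop_energy_content <= 0:
            raise ValueError("crop_energy_content must be positive")
        if self.kappa is not None and self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class DesignConfig:
    """Sampling design of the Monte Carlo experiment."""

    n_runs_per_set: int = 1000
    sobol_seed: int = 1234
    sobol_skip: int = 0

    def __post_init__(self) -> None:
        if self.n_runs_per_set <= 0:
            raise ValueError("n_runs_per_set must be positive")


@dataclass(frozen=True)
class AppConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    demand: DemandConfig = field(default_factory=DemandConfig)
    supply: SupplyConfig = field(default_factory=SupplyConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    targets: dict = field(default_factory=dict)  # overrides for TargetSpec


_SECTIONS = {
    "world": WorldConfig,
    "demand": DemandConfig,
    "supply": SupplyConfig,
    "design": DesignConfig,
}


def load_config(path: str | Path | None = None) -> AppConfig:
    """Build an :class:`AppConfig`, overriding defaults from a YAML file.

    Unknown sections or keys raise ``ValueError`` so typos do not pass
    silently. Tuple-valued fields may be given as YAML lists.
    """
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    kwargs = {}
    for section, payload in raw.items():
        if section == "targets":
            kwargs["targets"] = dict(payload or {})
            continue
        if section not in _SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        cls = _SECTIONS[section]
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        payload = payload or {}
        bad = set(payload) - valid
        if bad:
            raise ValueError(f"unknown keys in section {section!r}: {sorted(bad)}")
        coerced = {}
        for k, v in payload.items():
            if isinstance(v, list):
                v = tuple(v)
            if isinstance(v, dict):
                v = {int(kk) if str(kk).isdigit() else kk: _tuplify(vv) for kk, vv in v.items()}
            coerced[k] = v
        kwargs[section] = cls(**coerced)
    return AppConfig(**kwargs)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def with_overrides(cfg: AppConfig, **sections) -> AppConfig:
    """Return a copy of ``cfg`` with whole sections replaced."""
    return replace(cfg, **sections)
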