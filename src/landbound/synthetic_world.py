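"""Reproducible synthetic world: country baselines and exogenous paths.

The analysis needs, for every country, a year-2000 baseline (population,
income, diet, food-energy supply, cropland, suitable land, yield) plus
exogenous trajectories to 2050 (population, GDP per capita, and
potential crop yield under two climate variants). Real inputs of this
kind come from national statistics, SSP2-style projections and a crop
model; here they are emulated by a seeded generator that reproduces the
statistical structure the downstream screening relies on:

* baseline yield gaps between 0.3 and 0.9,
* a configurable share of countries below 2200 kcal cap-1 d-1,
* global cropland equal to ~12% of the 13400 Mha ice-free land surface,
* a baseline global mean yield (production / cropland) of 3.1 t ha-1.

The last two are imposed exactly by closed-form rescaling: a global
scale on residual (non-cereal) crop demand pins total production, and a
global scale on yields pins total cropland; both preserve all sampled
heterogeneity and each country's yield gap.

Countries are synthetic: identifiers ``C001``... carry no geography.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import N_YEARS, AppConfig, GroupThresholds, WorldConfig

GROUPS = (1, 3, 4)  # the model's group labelling has no group 2

_META_PREFIX = "# landbound-world "

_COLUMNS = [
    "country_id", "group", "pop_2000", "pop_growth", "gdp_pc_2000", "gdp_growth",
    "kcal_2000", "cereal_pc_2000", "meat_pc_2000", "milk_pc_2000",
    "other_crop_pc_2000", "other_supply_kcal", "cropland_2000", "suitable_land",
    "yield_2000", "potential_yield_2000",
]


def assign_group(gdp_pc_2000: float, meat_pc_2000: float,
                 thresholds: GroupThresholds | None = None) -> int:
    """Classify a country into consumption group 1, 3 or 4.

    Group 1: high income and high animal-product consumption (both inputs
    above their high thresholds). Group 4: countries without the means to
    raise animal-product consumption (both inputs below the low
    thresholds). Group 3: every transitioning country in between.
    """
    if gdp_pc_2000 <= 0 or meat_pc_2000 <= 0:
        raise ValueError("gdp_pc_2000 and meat_pc_2000 must be positive")
    t = thresholds or GroupThresholds()
    if gdp_pc_2000 > t.gdp_high and meat_pc_2000 > t.meat_high:
        return 1
    if gdp_pc_2000 < t.gdp_low and meat_pc_2000 < t.meat_low:
        return 4
    return 3


def potential_yield_path(potential_2000, variant: str, cfg: WorldConfig):
    """Potential-yield trajectory for one climate variant.

    A linear technological/CO2 trend lifts potential yield by
    ``potential_growth_2050`` over 2000-2050; the higher-warming variant
    ('rcp60') additionally suffers a quadratic late-century climate
    penalty, so it never exceeds the low-warming variant ('rcp26').
    """
    if variant not in ("rcp26", "rcp60"):
        raise ValueError(f"unknown climate variant {variant!r}")
    s = np.arange(N_YEARS) / (N_YEARS - 1.0)
    factor = 1.0 + cfg.potential_growth_2050 * s
    if variant == "rcp60":
        factor = factor - cfg.climate_penalty_2050 * s**2
    return np.asarray(potential_2000)[..., None] * factor


@dataclass(frozen=True)
class CountryRecord:
    """One country's baseline state and exogenous trajectories."""

    country_id: str
    group: int
    pop_path: np.ndarray  # millions, annual 2000-2050
    gdp_pc_path: np.ndarray  # constant USD per capita
    kcal_2000: float  # kcal cap-1 d-1
    cereal_pc_2000: float  # kg yr-1 (food cereals)
    meat_pc_2000: float
    milk_pc_2000: float
    cropland_2000: float  # Mha
    suitable_land: float  # Mha, moderate-to-very-high suitability
    yield_2000: float  # t ha-1
    potential_yield_paths: dict  # variant -> t ha-1 by year


@dataclass(frozen=True)
class WorldBaseline:
    """A full synthetic world: country table plus global constants."""

    frame: pd.DataFrame
    ice_free_land: float
    generator_seed: int
    potential_growth_2050: float
    climate_penalty_2050: float

    @property
    def n_countries(self) -> int:
        return len(self.frame)

    @property
    def world_cfg(self) -> WorldConfig:
        """Minimal config view used when reconstructing yield paths."""
        return WorldConfig(
            ice_free_land=self.ice_free_land,
            potential_growth_2050=self.potential_growth_2050,
            climate_penalty_2050=self.climate_penalty_2050,
        )

    @property
    def countries(self) -> list[CountryRecord]:
        t = np.arange(N_YEARS)
        out = []
        cfg = self.world_cfg
        for row in self.frame.itertuples(index=False):
            pot = {
                v: potential_yield_path(row.potential_yield_2000, v, cfg)
                for v in ("rcp26", "rcp60")
            }
            out.append(CountryRecord(
                country_id=row.country_id,
                group=int(row.group),
                pop_path=row.pop_2000 * (1.0 + row.pop_growth) ** t,
                gdp_pc_path=row.gdp_pc_2000 * (1.0 + row.gdp_growth) ** t,
                kcal_2000=row.kcal_2000,
                cereal_pc_2000=row.cereal_pc_2000,
                meat_pc_2000=row.meat_pc_2000,
                milk_pc_2000=row.milk_pc_2000,
                cropland_2000=row.cropland_2000,
                suitable_land=row.suitable_land,
                yield_2000=row.yield_2000,
                potential_yield_paths=pot,
            ))
        return out

    def to_csv(self, path: str | Path) -> None:
        """Write the world as a single CSV with a metadata comment line."""
        Path(path).write_text(self.to_csv_string())

    def to_csv_string(self) -> str:
        meta = {
            "ice_free_land": self.ice_free_land,
            "generator_seed": self.generator_seed,
            "potential_growth_2050": self.potential_growth_2050,
            "climate_penalty_2050": self.climate_penalty_2050,
        }
        buf = io.StringIO()
        buf.write(_META_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
        self.frame.to_csv(buf, index=False)
        return buf.getvalue()

    @classmethod
    def from_csv(cls, path: str | Path) -> "WorldBaseline":
        text = Path(path).read_text()
        first, _, rest = text.partition("\n")
        if not first.startswith(_META_PREFIX):
            raise ValueError(f"{path}: missing world metadata header")
        meta = json.loads(first[len(_META_PREFIX):])
        frame = pd.read_csv(io.StringIO(rest), float_precision="round_trip")
        missing = set(_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        world = cls(frame=frame[_COLUMNS], generator_seed=int(meta["generator_seed"]),
                    ice_free_land=float(meta["ice_free_land"]),
                    potential_growth_2050=float(meta["potential_growth_2050"]),
                    climate_penalty_2050=float(meta["climate_penalty_2050"]))
        validate_world(world)
        return world


def _check_positive_ranges(cfg: WorldConfig) -> None:
    for name in ("kcal_range", "meat_range", "milk_range", "gdp_range", "yield_range"):
        for lo, hi in getattr(cfg, name).values():
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: ranges must be positive with low <= high")
    for g, (lo, hi) in cfg.yield_gap_range.items():
        if not 0 < lo <= hi < 1:
            raise ValueError("yield_gap_range values must lie in (0, 1)")
    for name in ("gdp_growth_range", "pop_growth_range"):
        for lo, hi in getattr(cfg, name).values():
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid {name}: rates must be non-negative with low <= high")
    if cfg.suitable_multiple_range[0] < 1.0:
        raise ValueError("suitable land must be at least baseline cropland")


def _group_counts(n: int, shares: dict) -> dict:
    # guarantee one country per group, split the rest by largest remainder
    counts = {g: 1 for g in GROUPS}
    quota = {g: shares[g] * (n - 3) for g in GROUPS}
    for g in GROUPS:
        counts[g] += int(np.floor(quota[g]))
    rest = n - sum(counts.values())
    for g in sorted(GROUPS, key=lambda g: quota[g] - np.floor(quota[g]), reverse=True)[:rest]:
        counts[g] += 1
    return counts


def generate_world(n_countries: int | None = None, seed: int = 0,
                   config: AppConfig | None = None) -> WorldBaseline:
    """Generate a synthetic :class:`WorldBaseline`.

    Identical ``(n_countries, seed, config)`` yields bit-identical output;
    all randomness flows through one ``numpy`` generator seeded here.
    """
    cfg = (config or AppConfig()).world
    dem = (config or AppConfig()).demand
    n = n_countries if n_countries is not None else cfg.n_countries
    if n < 3:
        raise ValueError("n_countries must be >= 3")
    _check_positive_ranges(cfg)
    rng = np.random.default_rng(seed)

    counts = _group_counts(n, cfg.group_shares)
    group = np.repeat(list(counts), list(counts.values()))
    group = group[rng.permutation(n)]

    def by_group(ranges: dict) -> np.ndarray:
        lo = np.array([ranges[g][0] for g in group])
        hi = np.array([ranges[g][1] for g in group])
        return rng.uniform(lo, hi)

    # --- baseline food-energy supply, with the group-4 range stretched so
    # the expected share of countries under the low-supply threshold
    # equals the configured fraction
    kcal_ranges = {g: tuple(cfg.kcal_range[g]) for g in GROUPS}
    share4 = counts[4] / n
    p_within = min(1.0, cfg.low_supply_fraction / share4)
    lo4 = kcal_ranges[4][0]
    if lo4 >= cfg.low_supply_kcal or p_within <= 0:
        raise ValueError("group-4 kcal range must start below the low-supply threshold")
    kcal_ranges[4] = (lo4, lo4 + (cfg.low_supply_kcal - lo4) / p_within)
    kcal = by_group(kcal_ranges)
    low = kcal < cfg.low_supply_kcal
    if not low.any():  # enforce the invariant on unlucky small draws
        i = int(np.argmin(np.where(group == 4, kcal, np.inf)))
        kcal[i] = lo4

    meat = by_group(cfg.meat_range)
    milk = by_group(cfg.milk_range)
    gdp = by_group(cfg.gdp_range)
    gdp_growth = by_group(cfg.gdp_growth_range)
    pop_growth = by_group(cfg.pop_growth_range)
    yld = by_group(cfg.yield_range)
    gap = by_group(cfg.yield_gap_range)

    thr = cfg.thresholds
    for g, gd, mt in zip(group, gdp, meat):
        if assign_group(gd, mt, thr) != g:  # pragma: no cover - config guard
            raise ValueError("group draw ranges inconsistent with assignment thresholds")

    # --- population: heavy-tailed sizes normalised to the world total
    raw_pop = rng.lognormal(mean=np.log(15.0), sigma=1.3, size=n)
    pop = raw_pop * (cfg.world_pop_2000 / raw_pop.sum())

    # --- diet composition; the residual "other foods" supply is fixed over
    # time and makes the baseline energy identity exact
    other_share = rng.uniform(*cfg.other_supply_share_range, size=n)
    other_kcal = other_share * kcal
    animal_kcal = (meat * dem.meat_kcal_per_kg + milk * dem.milk_kcal_per_kg) / 365.0
    cereal_kcal = kcal - other_kcal - animal_kcal
    if (cereal_kcal <= 0).any():
        raise ValueError("kcal/consumption ranges leave no room for cereal supply")
    cereal_pc = cereal_kcal * 365.0 / dem.cereal_kcal_per_kg

    # --- demand-side closure: scale residual crop demand so baseline global
    # production equals cropland_share * ice_free_land * global_yield
    other_draw = rng.uniform(*cfg.other_crop_pc_range, size=n)
    feed_pc = meat * dem.feed_share_2000 * dem.fcr_2000
    base_mt = (cereal_pc + feed_pc) * pop / 1000.0  # Mt
    target_prod = cfg.cropland_share_2000 * cfg.ice_free_land * cfg.global_yield_2000
    scale = (target_prod - base_mt.sum()) / (other_draw * pop / 1000.0).sum()
    if scale <= 0:
        raise ValueError("baseline food+feed demand already exceeds target production")
    other_pc = other_draw * scale
    demand_mt = base_mt + other_pc * pop / 1000.0

    # --- supply-side closure: scale yields so baseline cropland (each
    # country self-sufficient) sums to the target share of ice-free land
    target_land = cfg.cropland_share_2000 * cfg.ice_free_land
    lam = (demand_mt / yld).sum() / target_land
    yld = yld * lam
    cropland = demand_mt / yld
    suitable = cropland * rng.uniform(*cfg.suitable_multiple_range, size=n)
    potential = yld / (1.0 - gap)

    frame = pd.DataFrame({
        "country_id": [f"C{i + 1:03d}" for i in range(n)],
        "group": group.astype(int),
        "pop_2000": pop,
        "pop_growth": pop_growth,
        "gdp_pc_2000": gdp,
        "gdp_growth": gdp_growth,
        "kcal_2000": kcal,
        "cereal_pc_2000": cereal_pc,
        "meat_pc_2000": meat,
        "milk_pc_2000": milk,
        "other_crop_pc_2000": other_pc,
        "other_supply_kcal": other_kcal,
        "cropland_2000": cropland,
        "suitable_land": suitable,
        "yield_2000": yld,
        "potential_yield_2000": potential,
    })
    world = WorldBaseline(frame=frame, ice_free_land=cfg.ice_free_land,
                          generator_seed=seed,
                          potential_growth_2050=cfg.potential_growth_2050,
                          climate_penalty_2050=cfg.climate_penalty_2050)
    validate_world(world, cfg)
    return world


def validate_world(world: WorldBaseline, cfg: WorldConfig | None = None) -> None:
    """Check the structural invariants of a world baseline."""
    f = world.frame
    if len(f) < 3:
        raise ValueError("world must contain at least 3 countries")
    if set(np.unique(f["group"])) - set(GROUPS):
        raise ValueError("unknown consumption group present")
    for g in GROUPS:
        if not (f["group"] == g).any():
            raise ValueError(f"no country in group {g}")
    pos_cols = ["pop_2000", "gdp_pc_2000", "kcal_2000", "cereal_pc_2000",
                "meat_pc_2000", "milk_pc_2000", "cropland_2000", "suitable_land",
                "yield_2000", "potential_yield_2000"]
    if not (f[pos_cols].to_numpy() > 0).all():
        raise ValueError("baseline columns must be strictly positive")
    if not (f["cropland_2000"] <= f["suitable_land"] * (1 + 1e-12)).all():
        raise ValueError("cropland_2000 exceeds suitable_land")
    gap = 1.0 - f["yield_2000"] / f["potential_yield_2000"]
    if not ((gap > 0) & (gap < 1)).all():
        raise ValueError("baseline yield must lie strictly below potential")
    if not (f["kcal_2000"] < 2200).any():
        raise ValueError("no low-food-supply country present")
    share = f["cropland_2000"].sum() / world.ice_free_land
    tol = 0.01 if cfg is None else max(0.01, 0.0)
    target = 0.12 if cfg is None else cfg.cropland_share_2000
    if abs(share - target) > tol:
        raise ValueError(f"global cropland share {share:.3f} far from {target}")
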