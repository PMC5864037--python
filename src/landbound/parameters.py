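"""Scenario parameter space: the 14 uncertain model parameters.

Each parameter has a current-trend setting and a [min, max] uncertainty
range; the Monte Carlo experiment samples the ranges uniformly with a
Sobol sequence, while the trend settings define the reference run.

All "(1/time)" parameters follow the linear-accrual convention: the
effect realised by year ``y`` is ``param * (y - 2000) / 100``.
"""
from __future__ import annotations

from dataclasses import dataclass, fields

#: (min, max) uncertainty range per sampled parameter, in sampling order.
PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "meat1": (-50.0, 50.0),
    "milk1": (-200.0, 50.0),
    "meat3": (0.0, 60.0),
    "milk3": (0.0, 90.0),
    "meat4": (5.0, 43.0),
    "milk4": (20.0, 70.0),
    "consL": (-60.0, 20.0),
    "cerealCon": (0.0, 0.4),
    "fcr_improvement": (0.0, 0.2),
    "feed_ratio_cap": (0.0, 0.2),
    "technology": (0.0, 2.0),
    "investments": (0.0, 1.7),
    "residualNV": (1.0, 20.0),
    "croplandDeg": (0.04, 0.1),
}

#: Setting that reproduces the average 2000-2010 trend for each parameter.
PARAM_TREND: dict[str, float] = {
    "meat1": -30.0,
    "milk1": -50.0,
    "meat3": 45.0,
    "milk3": 45.0,
    "meat4": 15.0,
    "milk4": 45.0,
    "consL": 0.0,
    "cerealCon": 0.0,
    "fcr_improvement": 0.2,
    "feed_ratio_cap": 0.0,
    "technology": 1.7,
    "investments": 1.7,
    "residualNV": 10.0,
    "croplandDeg": 0.05,
}

PARAM_NAMES: tuple[str, ...] = tuple(PARAM_BOUNDS)

#: Experiment sets. Set A: current-policy bioenergy (74 EJ by 2050, 3.5%
#: first generation) with the higher-warming yield variant; set B: the
#: stringent-mitigation pathway (125 EJ, 7%) with the low-warming variant.
SET_SETTINGS: dict[str, dict] = {
    "A": {"total_bioenergy_2050": 74.0, "first_gen_share_2050": 0.035, "climate_variant": "rcp60"},
    "B": {"total_bioenergy_2050": 125.0, "first_gen_share_2050": 0.07, "climate_variant": "rcp26"},
}


@dataclass(frozen=True)
class ScenarioParameters:
    """One sampled point of the 14-dimensional parameter space.

    ``set_id`` ('A' or 'B') fixes the bioenergy pathway and the climate
    variant of the potential-yield projection jointly; it is not sampled.
    """

    meat1: float
    milk1: float
    meat3: float
    milk3: float
    meat4: float
    milk4: float
    consL: float
    cerealCon: float
    fcr_improvement: float
    feed_ratio_cap: float
    technology: float
    investments: float
    residualNV: float
    croplandDeg: float
    set_id: str = "A"

    def __post_init__(self) -> None:
        if self.set_id not in SET_SETTINGS:
            raise ValueError(f"unknown set_id {self.set_id!r}")
        for name, (lo, hi) in PARAM_BOUNDS.items():
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")

    @classmethod
    def trend(cls, set_id: str = "A") -> "ScenarioParameters":
        """The reference parameterisation reproducing 2000-2010 trends."""
        return cls(set_id=set_id, **PARAM_TREND)

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
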