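"""Demand model: consumption anchors, caps, cereal boost, feed, energy."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from landbound.config import DemandConfig
from landbound.demand import (
    CONSUMPTION_ANCHORS,
    ConsumptionParams,
    EnergyDensities,
    FeedParams,
    apply_consumption_limit,
    cereal_boost_factor,
    consumption_2050,
    feed_demand,
    food_energy_supply,
    percap_animal_consumption,
)

ANCHOR_CASES = [
    (commodity, group, theta, outcome)
    for (commodity, group), (thetas, outcomes) in CONSUMPTION_ANCHORS.items()
    for theta, outcome in zip(thetas, outcomes)
]


@pytest.mark.parametrize("commodity, group, theta, outcome", ANCHOR_CASES)
def test_2050_consumption_anchors_exact(commodity, group, theta, outcome):
    """All 18 printed (setting -> 2050 outcome) anchors reproduce exactly
    at reference income."""
    value = percap_animal_consumption(commodity, group, theta, 2050, income_index=1.0)
    assert value == pytest.approx(outcome, abs=1e-9)


def test_baseline_anchoring_at_2000():
    """At 2000 the curve returns the group baseline for any setting/income."""
    for theta in (0.0, 45.0, 60.0):
        for idx in (0.6, 1.0, 1.4):
            assert percap_animal_consumption("meat", 3, theta, 2000, idx) == 51.0
    assert percap_animal_consumption("meat", 4, 15.0, 2000) == 22.0
    assert percap_animal_consumption("milk", 1, -50.0, 2000) == 200.0


def test_consumption_monotone_in_theta():
    for (commodity, group), (thetas, _) in CONSUMPTION_ANCHORS.items():
        grid = np.linspace(thetas[0], thetas[-1], 25)
        vals = [percap_animal_consumption(commodity, group, t, 2035, 1.1) for t in grid]
        assert np.all(np.diff(vals) >= -1e-12)


def test_theta_out_of_range_rejected():
    with pytest.raises(ValueError):
        percap_animal_consumption("meat", 1, 60.0, 2050)
    with pytest.raises(ValueError):
        consumption_2050("milk", 4, 80.0)


@pytest.mark.parametrize(
    "meat_in, milk_in, consL, meat_out, milk_out",
    [
        (130.0, 200.0, 0.0, 122.5, 200.0),  # trend cap: meat only
        (100.0, 300.0, -60.0, 62.5, 180.0),  # strictest cap
        (50.0, 100.0, 20.0, 50.0, 100.0),  # cap not binding
        (150.0, 100.0, 20.0, 142.5, 100.0),  # loosest meat cap
    ],
)
def test_consumption_limit(meat_in, milk_in, consL, meat_out, milk_out):
    meat, milk = apply_consumption_limit(meat_in, milk_in, consL)
    assert meat == pytest.approx(meat_out)
    assert milk == pytest.approx(milk_out)
    assert meat <= meat_in and milk <= milk_in


@pytest.mark.parametrize(
    "kcal, cerealCon, year, factor",
    [
        (2100.0, 0.4, 2050, 1.20),  # +20% in low-supply countries by 2050
        (2500.0, 0.4, 2050, 1.00),  # threshold not met
        (2100.0, 0.2, 2050, 1.10),  # linear accrual: 0.2 * 50/100
        (2100.0, 0.4, 2000, 1.00),  # no elapsed time
    ],
)
def test_cereal_boost_factor(kcal, cerealCon, year, factor):
    assert float(cereal_boost_factor(kcal, cerealCon, year)) == pytest.approx(factor)


def test_feed_demand_improvement_ratio():
    """fcr improvement at its maximum cuts 2050 feed demand to 90% of the
    no-improvement level (the printed 1461/1623 Mt ratio)."""
    fast = FeedParams(fcr_improvement=0.2, feed_ratio_cap=0.0)
    none = FeedParams(fcr_improvement=0.0, feed_ratio_cap=0.0)
    ratio = feed_demand(100.0, 2050, fast) / feed_demand(100.0, 2050, none)
    assert float(ratio) == pytest.approx(0.90, abs=1e-12)


def test_feed_demand_edge_cases():
    p = FeedParams(fcr_improvement=0.0, feed_ratio_cap=0.0)
    assert float(feed_demand(0.0, 2037, p)) == 0.0
    # parameters off: baseline relation production * share * fcr
    assert float(feed_demand(10.0, 2050, p)) == pytest.approx(10.0 * 0.25 * 10.5)
    with pytest.raises(ValueError):
        feed_demand(-1.0, 2050, p)


def test_feed_ratio_cap_raises_2050_feed_by_about_40pct():
    """The maximum feed-share growth raises 2050 feed demand ~39% above the
    trend level (directional, soft: the printed 2037/1461 Mt ratio)."""
    capped = FeedParams(fcr_improvement=0.2, feed_ratio_cap=0.2)
    trend = FeedParams(fcr_improvement=0.2, feed_ratio_cap=0.0)
    ratio = float(feed_demand(100.0, 2050, capped) / feed_demand(100.0, 2050, trend))
    assert ratio == pytest.approx(2037.0 / 1461.0, rel=0.10)


def test_food_energy_supply():
    d = EnergyDensities(cereal_kcal_per_kg=3000.0)
    assert float(food_energy_supply(0.0, 0.0, 0.0, d, 0.0)) == 0.0
    expected = 150.0 * 3000.0 / 365.0
    assert float(food_energy_supply(150.0, 0.0, 0.0, d, 0.0)) == pytest.approx(expected)
    with pytest.raises(ValueError):
        food_energy_supply(-1.0, 0.0, 0.0, d)
    with pytest.raises(ValueError):
        EnergyDensities(cereal_kcal_per_kg=-1.0)


def test_food_energy_supply_baseline_identity(reference_world):
    """Baseline consumptions return each generated country's kcal_2000: the
    residual supply term is the exact calibration closure."""
    f = reference_world.frame
    kcal = food_energy_supply(f["cereal_pc_2000"], f["meat_pc_2000"], f["milk_pc_2000"],
                              EnergyDensities(), f["other_supply_kcal"])
    assert np.allclose(kcal, f["kcal_2000"], rtol=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    meat=st.floats(0.0, 300.0),
    milk=st.floats(0.0, 400.0),
    consL=st.floats(-60.0, 20.0),
)
def test_limit_never_increases_and_meat_bound_holds(meat, milk, consL):
    m, k = apply_consumption_limit(meat, milk, consL)
    assert m <= meat + 1e-12 and k <= milk + 1e-12
    assert m <= 122.5 + consL + 1e-12
    assert k <= 240.0 + consL + 1e-12


def test_cap_dominance_at_strictest_limit():
    """With consL at its minimum no 2050 consumption exceeds 62.5 kg meat."""
    for (commodity, group), (thetas, _) in CONSUMPTION_ANCHORS.items():
        if commodity != "meat":
            continue
        raw = percap_animal_consumption("meat", group, thetas[-1], 2050, 1.4)
        capped, _ = apply_consumption_limit(raw, 0.0, -60.0)
        assert capped <= 62.5


def test_consumption_params_validation():
    good = dict(meat1=0.0, milk1=0.0, meat3=30.0, milk3=30.0, meat4=20.0,
                milk4=40.0, consL=0.0, cerealCon=0.1)
    ConsumptionParams(**good)
    with pytest.raises(ValueError):
        ConsumptionParams(**{**good, "meat1": 60.0})
    with pytest.raises(ValueError):
        ConsumptionParams(**{**good, "cerealCon": 0.5})


def test_national_energy_supply_monotone_in_parameters(prepared_reference,
                                                       calibrated_supply):
    """2050 minimum national food-energy supply is non-decreasing in the
    group-4 consumption parameters and in cerealCon."""
    from landbound.parameters import PARAM_TREND, ScenarioParameters
    from landbound.simulate import simulate_run

    def min_kcal(**over):
        p = ScenarioParameters(set_id="A", **{**PARAM_TREND, **over})
        return simulate_run(prepared_reference, p,
                            supply_cfg=calibrated_supply).min_kcal_2050

    for name, lo, hi in [("meat4", 5.0, 43.0), ("milk4", 20.0, 70.0),
                         ("cerealCon", 0.0, 0.4)]:
        vals = [min_kcal(**{name: v}) for v in np.linspace(lo, hi, 4)]
        assert np.all(np.diff(vals) >= -1e-9), name
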