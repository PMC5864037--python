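"""Shared fixtures: reference world, calibrated supply, screening ensemble."""
from __future__ import annotations

import pytest

from landbound.config import DemandConfig, SupplyConfig
from landbound.experiment import SamplingDesign, run_experiment
from landbound.simulate import calibrate_kappa, prepare_world
from landbound.synthetic_world import generate_world

REFERENCE_SEED = 1
REFERENCE_N = 150


@pytest.fixture(scope="session")
def reference_world():
    """The packaged reference world: 150 countries, seed 1."""
    return generate_world(REFERENCE_N, seed=REFERENCE_SEED)


@pytest.fixture(scope="session")
def prepared_reference(reference_world):
    return prepare_world(reference_world)


@pytest.fixture(scope="session")
def calibrated_supply(prepared_reference) -> SupplyConfig:
    """Supply config with kappa root-found to the 2050 yield anchor."""
    kappa = calibrate_kappa(prepared_reference)
    return SupplyConfig(kappa=kappa)


@pytest.fixture(scope="session")
def demand_cfg() -> DemandConfig:
    return DemandConfig()


@pytest.fixture(scope="session")
def small_world():
    return generate_world(12, seed=7)


@pytest.fixture(scope="session")
def screening_ensemble(prepared_reference, calibrated_supply):
    """The scaled-down screening ensemble: 2 sets x 1000 Sobol runs."""
    design = SamplingDesign(n_runs_per_set=1000)
    return run_experiment(prepared_reference, design, supply_cfg=calibrated_supply)
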