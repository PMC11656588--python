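import numpy as np
import pytest

from herdspace.economics import EconomicConfig
from herdspace.milk_model import MilkModelConfig, WilminkCurve
from herdspace.pipeline import RunConfig, run_simulation
from herdspace.repro_model import ReproductionConfig, ReproductiveDraws

ZERO_SDS = {
    "primiparous": WilminkCurve(0.0, 0.0, 0.0, 0.0),
    "multiparous": WilminkCurve(0.0, 0.0, 0.0, 0.0),
}


def deterministic_milk_config(**overrides) -> MilkModelConfig:
    """Milk config with every per-cow sd collapsed to zero."""
    defaults = dict(curve_sds=ZERO_SDS, scenario_effect_sd=0.0)
    defaults.update(overrides)
    return MilkModelConfig(**defaults)


def cancellation_run_config(n_cows: int = 20, seed: int = 3) -> RunConfig:
    """Zero scenario effect + identical conception distributions per scenario."""
    milk = deterministic_milk_config(
        curve_sds=MilkModelConfig().curve_sds, scenario_effect=0.0
    )
    repro = ReproductionConfig(
        conception={
            ("control", "primiparous"): (95.0, 12.0),
            ("high", "primiparous"): (95.0, 12.0),
            ("control", "multiparous"): (120.0, 18.0),
            ("high", "multiparous"): (120.0, 18.0),
        }
    )
    return RunConfig(seed=seed, n_cows=n_cows, milk_model=milk, reproduction=repro)


def fixed_draws(**overrides) -> ReproductiveDraws:
    """Hand-set reproductive draws for timeline arithmetic tests."""
    defaults = dict(
        conception={
            ("control", "primiparous"): 82,
            ("high", "primiparous"): 155,
            ("control", "multiparous"): 108,
            ("high", "multiparous"): 133,
        },
        gestation=280,
        dry_period=51,
        exit_dims=(153, 60, 250, 31, 305),
    )
    defaults.update(overrides)
    return ReproductiveDraws(**defaults)


@pytest.fixture
def milk_config() -> MilkModelConfig:
    return MilkModelConfig()


@pytest.fixture
def repro_config() -> ReproductionConfig:
    return ReproductionConfig()


@pytest.fixture
def econ_config() -> EconomicConfig:
    return EconomicConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def calibration_run():
    """Shipped-default simulation used for the qualitative pattern checks."""
    return run_simulation(RunConfig(seed=20407, n_cows=600))
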