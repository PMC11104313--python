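import numpy as np
import pytest

from competing_critics import CriticParams, SimulationConfig, run_replicates


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def stationary_result():
    """Default-parameter single-state run at modest replicate count."""
    return run_replicates(SimulationConfig(replicates=500, trials=100, seed=101))


@pytest.fixture(scope="session")
def igt_result():
    return run_replicates(SimulationConfig(task="igt", replicates=500, trials=100, seed=102))


@pytest.fixture(scope="session")
def two_stage_result():
    params = CriticParams(gamma=0.9)
    return run_replicates(
        SimulationConfig(task="two_stage", params=params, replicates=500, trials=80, seed=103)
    )


@pytest.fixture(scope="session")
def market_result():
    return run_replicates(SimulationConfig(task="market", replicates=500, trials=120, seed=104))
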