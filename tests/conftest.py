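import numpy as np
import pytest

from idirt.pipeline import run_pipeline
from idirt.simulate import NOISE_FREE, default_scenario, simulate


@pytest.fixture(scope="session")
def sim_default():
    """One default-scenario simulation shared across tests (seed 11)."""
    scenario = default_scenario(seed=11)
    return simulate(scenario)


@pytest.fixture(scope="session")
def sim_noise_free():
    scenario = default_scenario(seed=5, noise=NOISE_FREE)
    return simulate(scenario)


@pytest.fixture(scope="session")
def pipeline_default(sim_default):
    sc = sim_default.scenario
    return run_pipeline(sim_default.spectra, sim_default.psms,
                        sim_default.groups, list(sc.conditions))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
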