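import numpy as np
import pytest

from qifmrr import Cohort, SimulationScenario, ThetaParams, generate_cohort

THETA_TRUE = ThetaParams(3.0, -5.0, 1.5, 0.1, 5.5)
PSI_TRUE = (1.5, 0.1, 5.5)


@pytest.fixture
def theta_true():
    return THETA_TRUE


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_cohort_factory(rng):
    """Small random cohorts (not from the generative model) for algebraic oracles."""

    def make(n=5, K=3):
        return Cohort(
            subject_ids=list(range(n)),
            states=rng.normal(0.5, 0.3, size=(n, K)),
            actions=rng.integers(0, 4, size=(n, K)).astype(float),
            responses=rng.normal(0.0, 1.0, size=(n, K)),
        )

    return make


@pytest.fixture
def small_scenario():
    return SimulationScenario(n=40, K=6, rho=0.3, seed=7)


@pytest.fixture
def small_generated(small_scenario):
    return generate_cohort(small_scenario)
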