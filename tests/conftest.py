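import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dbtlearn as dl
from dbtlearn._utils import derive_seed
from dbtlearn.benchmark import BenchmarkProblem, latin_hypercube, simulate_dbtl

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


class StubModel:
    """Minimal model whose predictive mean is a given function and variance 0.

    With a maximization objective at alpha = 0 the surrogate equals the
    function exactly, which lets sampler tests target known densities.
    """

    def __init__(self, fn, dim):
        self.fn = fn
        self.feature_names = [f"x{i + 1}" for i in range(dim)]
        self.n_responses = 1

    def predict_moments(self, X, response_index=0):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.fn(X), np.zeros(len(X))


@pytest.fixture(scope="session")
def fe_problem():
    return BenchmarkProblem("FE", 2)


@pytest.fixture(scope="session")
def fe_training(fe_problem):
    """16-point Latin-hypercube design on the easy landscape (noise-free)."""
    X = latin_hypercube(16, fe_problem.bounds, seed=7)
    y = fe_problem.evaluate(X)
    return dl.TrainingSet(X, y[:, None], ["x1", "x2"], ["response"])


@pytest.fixture(scope="session")
def fe_model(fe_training):
    """Ensemble trained once and shared across recommendation tests."""
    return dl.fit_ensemble(
        fe_training, learners=dl.fast_learners(), n_samples=1500, burn_in=400, seed=7
    )


@pytest.fixture(scope="session")
def fe_campaigns(fe_problem):
    """Ten repeated 10-cycle simulated DBTL campaigns on the easy landscape.

    Desk-scale sampler sizes; shared by the trend and acceptance suites so
    the simulation runs only once.
    """
    return [
        simulate_dbtl(
            fe_problem,
            n_cycles=10,
            seed=derive_seed(11, "campaign", i),
            n_samples=1000,
            burn_in=300,
            pi_draws=600,
            pi_burn=200,
        )
        for i in range(10)
    ]


@pytest.fixture
def stub_model_factory():
    return StubModel
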