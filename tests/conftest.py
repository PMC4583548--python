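import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import growdom as gd

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Shared worked-example parameters (exponential growth, block IC).
WORKED_EXAMPLE = dict(L0=1.0, alpha=0.1, C0=1.0, gamma=0.2)


def four_generation_problem(D, k=(0.1, 0.2, 0.3, 0.0), m=2):
    return gd.Problem(
        growth=gd.make_exponential(WORKED_EXAMPLE["L0"], WORKED_EXAMPLE["alpha"]),
        lineage=gd.LineageModel(k=k, m=m),
        D=D,
        ic=gd.InitialCondition.block(WORKED_EXAMPLE["C0"], WORKED_EXAMPLE["gamma"]),
    )


@pytest.fixture(scope="session")
def failure_problem():
    """Slow diffusion: colonization fails by t = 20."""
    return four_generation_problem(1e-5)


@pytest.fixture(scope="session")
def success_problem():
    """Faster diffusion: colonization succeeds by t = 20."""
    return four_generation_problem(1e-2)


@pytest.fixture(scope="session")
def equal_rates_problem():
    """Equal proliferation rates across all four generations."""
    return four_generation_problem(1e-2, k=(0.1, 0.1, 0.1, 0.1))


@pytest.fixture
def rng():
    return np.random.default_rng(20150925)
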