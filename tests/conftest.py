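import numpy as np
import pytest

from musclevol import (
    CohortSpec,
    PhantomSpec,
    default_quadriceps,
    generate_cohort,
    run_interval_experiment,
)


@pytest.fixture(scope="session")
def frustum_spec():
    """Circular frustum, radius 1 → 2 cm over 3 cm: volume 7π/... closed form."""
    return PhantomSpec(family="frustum", parameters={"r0": 1.0, "r1": 2.0}, length=3.0)


@pytest.fixture(scope="session")
def quadratic_spec():
    """A(z) = 60 + 8z − 0.4z² on [0, 20]: smooth convex profile."""
    return PhantomSpec(
        family="quadratic_area",
        parameters={"c0": 60.0, "c1": 8.0, "c2": -0.4},
        length=20.0,
    )


@pytest.fixture(scope="session")
def quadriceps_spec():
    return default_quadriceps()


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort (n=38, seed 1)."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def cohort_estimates(default_cohort):
    ests = []
    for series, _ in default_cohort:
        ests.extend(run_interval_experiment(series))
    return ests


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
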