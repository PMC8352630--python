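import numpy as np
import pytest

from pmvalsim import CalibrationParams, LPDistribution, ScenarioSpec, generate_dataset
from pmvalsim.fixtures import make_fixture

DVT_LP = LPDistribution(mu=-1.75, sigma=1.47)


@pytest.fixture(scope="session")
def dvt_lp() -> LPDistribution:
    """LP distribution reported for the worked DVT diagnostic model."""
    return DVT_LP


@pytest.fixture(scope="session")
def perfect_cohort():
    """N=500 cohort from the well-calibrated DVT generator."""
    return make_fixture("perfect", seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """N=20 cohort guaranteed to contain both outcome classes."""
    return make_fixture("tiny", seed=1)


@pytest.fixture(scope="session")
def random_cohorts():
    """A batch of small random cohorts spanning sizes and event rates."""
    cohorts = []
    for seed, (mu, sigma, n) in enumerate(
        [(-1.75, 1.47, 80), (0.0, 1.0, 150), (-2.0, 0.5, 200), (1.0, 0.3, 60)]
    ):
        spec = ScenarioSpec(
            lp=LPDistribution(mu, sigma), calib=CalibrationParams(), n=n, seed=seed
        )
        data = generate_dataset(spec)
        if 0 < data.n_events < data.n:
            cohorts.append(data)
    return cohorts
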