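import numpy as np
import pandas as pd
import pytest

from ildgapm import Cohort, SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=20260926)


@pytest.fixture(scope="session")
def small_cohort(default_config) -> Cohort:
    """A study-sized synthetic cohort (n=179) under the default conditions."""
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def large_cohort() -> Cohort:
    """A large synthetic cohort for asymptotic checks."""
    return generate_cohort(SimulationConfig(n_patients=100_000, seed=8841))


@pytest.fixture()
def cohort_csv(tmp_path, small_cohort):
    from ildgapm import write_cohort

    path = tmp_path / "cohort.csv"
    write_cohort(small_cohort, path)
    return path


@pytest.fixture(scope="session")
def censored_sample():
    """A generic right-censored sample with a prognostic predictor."""
    rng = np.random.default_rng(314)
    n = 300
    x = rng.normal(size=n)
    t_event = rng.exponential(600.0 * np.exp(-0.6 * x))
    c = rng.exponential(800.0, n)
    times = np.minimum(np.minimum(t_event, c), 1500.0) + 0.5
    events = (t_event <= c) & (t_event <= 1500.0)
    return times, events, x
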