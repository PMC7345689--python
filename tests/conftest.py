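import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import aircrossover as ac

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20200612)


@pytest.fixture(scope="session")
def toronto_totals():
    return ac.toronto_visit_totals()


@pytest.fixture(scope="session")
def small_simulation():
    """Two simulated years with a known PM2.5 effect at lag 1 (shared, read-only)."""
    truth = ac.SimulationTruth(seed=11, phi=1.2)
    rng = np.random.default_rng(11)
    exposures = ac.simulate_exposures(truth, 731, rng)
    iqr = ac.interquartile_range(exposures["pm25_ugm3"]).iqr
    truth.beta_per_unit = float(np.log(1.15) / iqr)
    visits = ac.simulate_counts(exposures, truth, rng)
    return truth, exposures, visits


@pytest.fixture
def visits_csv(tmp_path, small_simulation):
    _, _, visits = small_simulation
    path = tmp_path / "visits.csv"
    ac.write_visit_counts(visits, path)
    return path


@pytest.fixture
def exposures_csv(tmp_path, small_simulation):
    _, exposures, _ = small_simulation
    path = tmp_path / "exposures.csv"
    ac.write_daily_exposures(exposures, path)
    return path
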