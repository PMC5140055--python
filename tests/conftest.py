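import numpy as np
import pandas as pd
import pytest

from gliolnc import synthdata


@pytest.fixture(scope="session")
def fixture_set():
    """Catalog filter fixtures with planted verdicts."""
    return synthdata.make_filter_fixtures(seed=0)


@pytest.fixture(scope="session")
def small_lgg_cohort():
    """A reduced LGG-like cohort for fast survival-pipeline unit tests."""
    return synthdata.simulate_lgg_cohort(
        n_samples=150, n_lncrnas=40, n_prognostic=4, seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def clinical_frame():
    """A small, fully valid clinical table."""
    n = 5
    return pd.DataFrame(
        {
            "sample": [f"s{i}" for i in range(n)],
            "time_days": [100.0, 250.0, 800.0, 40.0, 1500.0],
            "event": [1, 0, 1, 1, 0],
            "age": [40.0, 55.0, 61.0, 33.0, 47.0],
            "sex": ["male", "female", "male", "female", "male"],
            "grade": ["II", "III", "II", "III", "II"],
            "idh_mut": [1, 0, 1, 1, 0],
            "codel_1p19q": [0, 0, 1, 0, 0],
            "subtype": ["IDHmut", "IDHwt", "IDHmut-codel", "IDHmut", None],
        }
    )
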