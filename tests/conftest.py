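import numpy as np
import pytest

import trialscape as ts


@pytest.fixture(scope="session")
def country_table():
    return ts.load_country_table()


@pytest.fixture(scope="session")
def keywords():
    return ts.load_default_keywords()


def make_record(trial_id, countries, year=2010, sponsor=ts.INDUSTRY, name=None):
    return ts.TrialRecord(
        trial_id=trial_id,
        start_year=year,
        sponsor_type=sponsor,
        countries=frozenset(countries),
        sponsor_name=name,
    )


@pytest.fixture(scope="session")
def small_registry():
    """A small deterministic registry drawn at reduced volume."""
    config = ts.default_config(rate_scale=0.02, seed=123)
    return ts.generate_registry(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
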