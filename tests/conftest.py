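import dataclasses

import pytest
from hypothesis import settings

import ctdose

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def body_table():
    return ctdose.body_32cm_table()


@pytest.fixture(scope="session")
def f_table():
    return ctdose.default_f_factors()


@pytest.fixture(scope="session")
def default_cohort():
    """Default-calibrated synthetic cohort: n = 68 F / 66 M, seed 42."""
    return ctdose.generate_cohort()


@pytest.fixture(scope="session")
def default_frame(default_cohort, body_table, f_table):
    derived, failures = ctdose.derive_all(default_cohort, body_table, f_table)
    assert not failures
    return ctdose.cohort_frame(derived)


@pytest.fixture(scope="session")
def big_cohort():
    """Default calibration at n = 10,000 per sex (law-of-large-numbers checks)."""
    cfg = ctdose.default_config()
    cfg.female = dataclasses.replace(cfg.female, n=10_000)
    cfg.male = dataclasses.replace(cfg.male, n=10_000)
    return cfg, ctdose.generate_cohort(cfg)
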