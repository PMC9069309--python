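import numpy as np
import pandas as pd
import pytest

from mhq import default_config, generate_cohort, load_element_bank, load_rule_table


@pytest.fixture(scope="session")
def bank():
    return load_element_bank()


@pytest.fixture(scope="session")
def rules(bank):
    return load_rule_table(bank=bank)


@pytest.fixture(scope="session")
def small_cohort(bank):
    """1,000-record default cohort, shared across tests that only read it."""
    return generate_cohort(default_config(n=1000, seed=123), bank)


def make_record(bank, spectrum=9, problem=1, **overrides):
    """Rating dict with constant values per format plus per-element overrides."""
    ratings = {}
    for e in bank:
        ratings[e.element_id] = spectrum if e.format == "spectrum" else problem
    ratings.update(overrides)
    return ratings


@pytest.fixture(scope="session")
def best_record(bank):
    return make_record(bank, spectrum=9, problem=1)


@pytest.fixture(scope="session")
def worst_record(bank):
    return make_record(bank, spectrum=1, problem=9)
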