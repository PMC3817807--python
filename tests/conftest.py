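"""Shared fixtures: small synthetic cases and profiles built once per session."""

import pytest

from cytoprofile.diagnosis import build_cohort_profile
from cytoprofile.preprocess import preprocess_case
from cytoprofile.synth import cll_spec, generate_case, normal_spec


@pytest.fixture(scope="session")
def normal_table():
    """One healthy case with ground-truth population labels."""
    return generate_case(normal_spec(n_events=3000, seed=7))


@pytest.fixture(scope="session")
def normal_points(normal_table):
    return preprocess_case(normal_table)


@pytest.fixture(scope="session")
def normal_profile(normal_points):
    return build_cohort_profile([normal_points], "Normal", seed=0)


@pytest.fixture(scope="session")
def cll_points():
    """A kappa-restricted CLL case, preprocessed."""
    return preprocess_case(generate_case(cll_spec(dominance="kappa", n_events=3000, seed=11)))


@pytest.fixture(scope="session")
def cll_profile(cll_points):
    return build_cohort_profile([cll_points], "CLL", seed=0)
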