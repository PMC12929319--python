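"""Shared fixtures: toy value sets and small seed-fixed synthetic cohorts."""

import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from hsuvmix import SyntheticCohortConfig, ValueSet, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_value_set():
    """Small additive tariff used throughout: one decrement per level plus
    an any-problem constant."""
    return ValueSet(
        full_health=1.0,
        decrements={
            "mobility": {2: 0.1, 3: 0.4},
            "self_care": {2: 0.08, 3: 0.2},
            "usual_activities": {2: 0.03, 3: 0.09},
            "pain_discomfort": {2: 0.05, 3: 0.3},
            "anxiety_depression": {2: 0.06, 3: 0.2},
        },
        constants={"any_problem": 0.05},
    )


@pytest.fixture(scope="session")
def small_lmm_cohort():
    """150-patient cohort from an in-range linear model (no boundary mass),
    usable by every family."""
    cfg = SyntheticCohortConfig(
        n_patients=150,
        seed=11,
        family="lmm",
        true_params={
            "beta": {"intercept": 0.45, "sex": 0.05, "t_pre": 0.03, "t_post": -0.005},
            "sd_intercept": 0.08,
            "sd_slope": 0.0,
            "sd_resid": 0.06,
        },
    )
    cohort, truth = generate_cohort(cfg)
    assert cohort["hsuv"].between(-0.53, 1.0).all()
    return cohort, cfg


@pytest.fixture(scope="session")
def beta_cohort():
    """80-patient cohort from the mixed beta family at moderate SDs."""
    params = {
        "beta": {"intercept": -1.6, "sex": -0.2, "t_pre": -0.2, "t_post": 0.02},
        "sd_intercept": 0.3,
        "sd_slope": 0.3,
        "phi": 6.0,
    }
    cfg = SyntheticCohortConfig(
        n_patients=80, seed=3, family="beta", true_params=params
    )
    cohort, _ = generate_cohort(cfg)
    return cohort, params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
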