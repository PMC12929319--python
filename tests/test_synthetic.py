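"""Synthetic cohort generator: determinism, laws, and degenerate configs."""

import numpy as np
import pytest

from hsuvmix import SyntheticCohortConfig, generate_cohort, generate_covariates, generate_visits
from hsuvmix.errors import ConfigError
from hsuvmix.synthetic import TWOPART_TRUE_PARAMS, _visit_count_probs


def test_same_seed_gives_byte_identical_csv(tmp_path):
    cfg = SyntheticCohortConfig(n_patients=60, seed=42)
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(SyntheticCohortConfig(n_patients=60, seed=42))
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    a.to_csv(pa, index=False)
    b.to_csv(pb, index=False)
    assert pa.read_bytes() == pb.read_bytes()
    c, _ = generate_cohort(SyntheticCohortConfig(n_patients=60, seed=43))
    assert not a.equals(c)


def test_covariate_moments_tighten_with_n():
    # law of large numbers on the age mean and male fraction
    devs = []
    for n in (200, 20000):
        cfg = SyntheticCohortConfig(n_patients=n, seed=5)
        pats = generate_covariates(cfg)
        devs.append(
            abs(pats["age"].mean() - 50.0) / 14.2 + abs(pats["sex"].mean() - 0.63)
        )
    assert devs[1] < devs[0]


def test_forced_probabilities_degenerate():
    cfg = SyntheticCohortConfig(n_patients=50, seed=1, male_frac=1.0)
    pats = generate_covariates(cfg)
    assert (pats["sex"] == 1).all()
    assert set(pats["bmi_lt18"] + pats["bmi_gt30"]) <= {0, 1}  # exclusive categories


def test_visit_count_distribution_shape():
    probs = _visit_count_probs(SyntheticCohortConfig(n_patients=1, seed=1))
    assert probs.sum() == pytest.approx(1.0)
    assert probs[0] == pytest.approx(0.513)
    assert probs[1] == pytest.approx(0.227)
    assert len(probs) == 10
    # geometric tail decays at the configured ratio
    assert probs[3] / probs[2] == pytest.approx(0.6)


def test_single_visit_forced():
    cfg = SyntheticCohortConfig(n_patients=40, seed=2, p_one_visit=1.0, p_two_visits=0.0)
    pats = generate_covariates(cfg)
    visits = generate_visits(cfg, pats)
    assert len(visits) == 40
    assert visits.groupby("patient_id").size().eq(1).all()


def test_visit_times_within_follow_up_window():
    cfg = SyntheticCohortConfig(n_patients=500, seed=3)
    pats = generate_covariates(cfg)
    visits = generate_visits(cfg, pats)
    assert visits["time"].between(0.08, 29.5).all()
    # times sorted within patient
    assert visits.groupby("patient_id")["time"].apply(lambda s: s.is_monotonic_increasing).all()


def test_lmm_outcomes_degenerate_noise_free():
    cfg = SyntheticCohortConfig(
        n_patients=25, seed=4, family="lmm",
        true_params={"beta": {"intercept": 0.881},
                     "sd_intercept": 0.0, "sd_slope": 0.0, "sd_resid": 0.0},
    )
    cohort, _ = generate_cohort(cfg)
    assert np.allclose(cohort["hsuv"], 0.881)


def test_twopart_outcomes_emit_exact_ones():
    cfg = SyntheticCohortConfig(
        n_patients=400, seed=6, family="twopart_beta",
        true_params=dict(TWOPART_TRUE_PARAMS),
    )
    cohort, _ = generate_cohort(cfg)
    at_ceiling = cohort["hsuv"] == 1.0
    assert at_ceiling.any()
    assert cohort.loc[~at_ceiling, "hsuv"].lt(1.0).all()
    assert cohort["hsuv"].ge(-0.53).all()


def test_discretization_snaps_to_value_set_grid(toy_value_set):
    from hsuvmix import enumerate_grid

    cfg = SyntheticCohortConfig(
        n_patients=150, seed=8, family="twopart_beta",
        true_params=dict(TWOPART_TRUE_PARAMS),
        discretize_to_grid=True, value_set=toy_value_set,
    )
    cohort, _ = generate_cohort(cfg)
    grid = np.asarray(enumerate_grid(toy_value_set))
    interior = cohort["hsuv"].between(-0.53, 1.0, inclusive="neither")
    dists = np.abs(cohort.loc[interior, "hsuv"].to_numpy()[:, None] - grid[None, :]).min(axis=1)
    assert np.all(dists < 1e-9)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SyntheticCohortConfig(n_patients=10, male_frac=1.4)
    with pytest.raises(ConfigError):
        SyntheticCohortConfig(n_patients=10, bmi_probs=(0.5, 0.4, 0.2))
    with pytest.raises(ConfigError):
        generate_cohort(
            SyntheticCohortConfig(n_patients=5, family="beta", true_params={"beta": {}})
        )


def test_missing_family_parameter_named_in_error():
    cfg = SyntheticCohortConfig(
        n_patients=5, family="twopart_beta", true_params={"gamma": {"intercept": 0.0}}
    )
    with pytest.raises(ConfigError, match="beta"):
        generate_cohort(cfg)


def test_empty_cohort():
    cohort, meta = generate_cohort(SyntheticCohortConfig(n_patients=0, seed=1))
    assert len(cohort) == 0
    assert "hsuv" in cohort.columns
    assert meta["config"]["n_patients"] == 0


def test_covariate_missingness_rate():
    cfg = SyntheticCohortConfig(n_patients=3000, seed=9, covariate_missing_rate=0.1)
    pats = generate_covariates(cfg)
    frac = pats.drop(columns="patient_id").isna().mean().mean()
    assert frac == pytest.approx(0.1, abs=0.02)
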