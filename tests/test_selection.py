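"""Likelihood-ratio covariate selection and mixture class choice."""

import pytest

from hsuvmix import ModelSpec, SyntheticCohortConfig, generate_cohort
from hsuvmix.selection import (
    forward_select,
    select_aldvmm_classes,
    univariate_screen,
)

BASE = ModelSpec(family="lmm", covariates=())


@pytest.fixture(scope="module")
def cohort_with_effects():
    # moderate cohort where sex and age carry real effects and the
    # remaining candidates are null
    cfg = SyntheticCohortConfig(
        n_patients=400, seed=21,
        true_params={
            "beta": {"intercept": 0.7, "sex": 0.12, "age": -0.004,
                     "t_pre": 0.05, "t_post": -0.005},
            "sd_intercept": 0.15, "sd_slope": 0.1, "sd_resid": 0.1,
        },
    )
    cohort, _ = generate_cohort(cfg)
    return cohort


def test_empty_candidate_list_gives_empty_screen(cohort_with_effects):
    trace = univariate_screen(cohort_with_effects, BASE, [])
    assert trace.screen == []
    assert trace.screened == []


def test_screen_statistics_well_formed(cohort_with_effects):
    trace = univariate_screen(
        cohort_with_effects, BASE, ["sex", "age", "neoplasia", "donor_age"]
    )
    for entry in trace.screen:
        assert entry["lrt"] >= 0
        assert 0 <= entry["p"] <= 1
    kept = trace.screened
    assert "sex" in kept and "age" in kept  # strong true effects


def test_forward_selection_recovers_true_effects(cohort_with_effects):
    trace = univariate_screen(
        cohort_with_effects, BASE, ["sex", "age", "neoplasia", "donor_age"]
    )
    trace = forward_select(cohort_with_effects, BASE, trace=trace)
    assert set(trace.selected) >= {"sex", "age"}
    assert "neoplasia" not in trace.selected
    # entry p-values below the threshold, in entry order
    for step in trace.forward_steps:
        assert step["p_at_entry"] < 0.05


def test_forward_path_loglik_non_decreasing(cohort_with_effects):
    # each accepted step strictly improves the likelihood (LRT > 0)
    trace = univariate_screen(cohort_with_effects, BASE, ["sex", "age"])
    trace = forward_select(cohort_with_effects, BASE, trace=trace)
    assert len(trace.forward_steps) >= 1


def test_collinear_duplicate_enters_at_most_once(cohort_with_effects):
    df = cohort_with_effects.copy()
    df["sex_copy"] = df["sex"]
    trace = univariate_screen(df, BASE, ["sex", "sex_copy"])
    trace = forward_select(df, BASE, trace=trace)
    assert sorted(trace.selected).count("sex") + sorted(trace.selected).count(
        "sex_copy"
    ) == 1


def test_selection_invariant_to_row_order(cohort_with_effects):
    shuffled = cohort_with_effects.sample(frac=1.0, random_state=99).reset_index(drop=True)
    t1 = univariate_screen(cohort_with_effects, BASE, ["sex", "age", "neoplasia"])
    t2 = univariate_screen(shuffled, BASE, ["sex", "age", "neoplasia"])
    p1 = {e["candidate"]: e["p"] for e in t1.screen}
    p2 = {e["candidate"]: e["p"] for e in t2.screen}
    for name in p1:
        assert p1[name] == pytest.approx(p2[name], abs=1e-6)


def test_bmi_pair_candidate_uses_two_degrees_of_freedom(cohort_with_effects):
    trace = univariate_screen(cohort_with_effects, BASE, [("bmi_lt18", "bmi_gt30")])
    assert trace.screen[0]["df"] == 2


def test_no_candidate_passing_keeps_base_model(cohort_with_effects):
    trace = forward_select(cohort_with_effects, BASE, screened=["neoplasia"])
    assert trace.selected == []


def test_trace_serialises_to_json(tmp_path, cohort_with_effects):
    trace = univariate_screen(cohort_with_effects, BASE, ["sex"])
    trace = forward_select(cohort_with_effects, BASE, trace=trace)
    path = tmp_path / "trace.json"
    trace.to_json(path)
    import json

    data = json.loads(path.read_text())
    assert data["selected"] == trace.selected
    assert any("screen sex" in line for line in trace.log_lines())


def test_class_count_single_option_returned():
    cfg = SyntheticCohortConfig(
        n_patients=80, seed=13, family="lmm",
        true_params={"beta": {"intercept": 0.5, "t_pre": 0.0, "t_post": 0.0},
                     "sd_intercept": 0.08, "sd_slope": 0.0, "sd_resid": 0.08},
    )
    cohort, _ = generate_cohort(cfg)
    spec = ModelSpec(family="aldvmm", covariates=(), psi1=0.95, random_slope=False)
    k, table = select_aldvmm_classes(cohort, spec, (1,), seed=2)
    assert k == 1
    assert list(table["k"]) == [1]


def test_two_class_data_selects_two_classes_by_bic():
    cfg = SyntheticCohortConfig(
        n_patients=250, seed=5, family="aldvmm",
        true_params={"beta": {"sex": 0.05, "t_pre": 0.0, "t_post": 0.0},
                     "class_intercepts": [0.35, 0.85], "class_sigmas": [0.08, 0.07],
                     "class_probs": [0.35, 0.65], "sd_intercept": 0.05, "psi1": 0.93},
    )
    cohort, _ = generate_cohort(cfg)
    spec = ModelSpec(family="aldvmm", covariates=("sex",), psi1=0.93,
                     random_slope=False, n_starts=3)
    k, table = select_aldvmm_classes(cohort, spec, (1, 2), seed=3)
    assert k == 2
    bics = dict(zip(table["k"], table["bic"]))
    assert bics[2] < bics[1]
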