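import math

import numpy as np
import pandas as pd
import pytest

import placebayes as pb
from placebayes.errors import InputError, InsufficientDataError, MissingCellError, ParameterError


def _subject_frame(subject_id="s1", group="HTP", cells=None):
    rows = []
    for (phase, condition), values in cells.items():
        for i, v in enumerate(values):
            rows.append(
                dict(subject_id=subject_id, group=group, phase=phase,
                     condition=condition, trial=i + 1, temperature_c=45.0, vas=v)
            )
    return pd.DataFrame(rows)


def test_placebo_effect_is_control_minus_placebo():
    trials = _subject_frame(cells={
        ("conditioning", "placebo"): [30, 32],
        ("conditioning", "control"): [70, 68],
        ("test", "placebo"): [43, 43, 43],
        ("test", "control"): [50, 50, 50],
    })
    s = pb.summarize_subject(trials, "s1")
    assert s.placebo_effect_observed == pytest.approx(7.0)
    assert s.sd_test_placebo == 0.0


def test_identical_test_conditions_give_zero_effect():
    trials = _subject_frame(cells={
        ("conditioning", "placebo"): [30, 31],
        ("conditioning", "control"): [69, 70],
        ("test", "placebo"): [48, 52],
        ("test", "control"): [52, 48],
    })
    assert pb.summarize_subject(trials, "s1").placebo_effect_observed == pytest.approx(0.0)


def test_descriptive_sd_uses_n_minus_1():
    trials = _subject_frame(cells={
        ("conditioning", "placebo"): [20, 30, 40],
        ("conditioning", "control"): [70, 70],
        ("test", "placebo"): [50, 50],
        ("test", "control"): [50, 50],
    })
    s = pb.summarize_subject(trials, "s1")
    assert s.sd_cond_placebo == pytest.approx(10.0)  # not the ML sqrt(200/3)


def test_missing_cell_raises():
    trials = _subject_frame(cells={("conditioning", "placebo"): [30, 31]})
    with pytest.raises(MissingCellError):
        pb.summarize_subject(trials, "s1")


def _summaries(rows):
    return pd.DataFrame(rows, columns=["subject_id", "group", "sd_cond_placebo"]).assign(
        placebo_effect_observed=0.0
    )


def test_subsample_cutoffs_follow_group_rules():
    summaries = _summaries([
        ("h_keep", "HTP", 13.63),  # below the 19.60 SD ceiling
        ("h_edge", "HTP", 19.60),  # variance 384.16 sits above the 384.08 cut -> excluded
        ("h_out", "HTP", 25.0),
        ("l_keep", "LTP", 22.46),  # above the 13.96 SD floor
        ("l_out", "LTP", 10.0),
    ])
    flagged = pb.apply_subsample_cutoffs(summaries)
    assert flagged.set_index("subject_id").in_subsample.to_dict() == {
        "h_keep": True, "h_edge": False, "h_out": False, "l_keep": True, "l_out": False,
    }
    # only a flag column is added; nothing else changes
    pd.testing.assert_frame_equal(flagged.drop(columns="in_subsample"), summaries)


def test_subsample_rejects_unknown_group():
    with pytest.raises(InputError):
        pb.apply_subsample_cutoffs(_summaries([("x", "MTP", 15.0)]))


def test_pearson_perfect_linear_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pb.pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert pb.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)


def test_pearson_recovers_known_correlation(rng):
    n = 1000
    x = rng.normal(size=n)
    y = x + rng.normal(scale=1.0, size=n)  # theoretical r = 1/sqrt(2)
    r, p = pb.pearson_correlation(x, y)
    se = (1 - 0.5) / math.sqrt(n - 3)
    assert abs(r - 1 / math.sqrt(2)) < 3 * se
    assert p < 1e-10


def test_pearson_degenerate_inputs():
    with pytest.raises(ParameterError):
        pb.pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(InsufficientDataError):
        pb.pearson_correlation([1.0, 2.0], [1.0, 2.0])


def _regression_tables(rng, noise=0.0, n=40):
    sigma_p = rng.uniform(5, 25, size=n)
    sigma_l = rng.uniform(5, 25, size=n)
    effect = 15.005 - 0.883 * sigma_p + 0.562 * sigma_l + rng.normal(0, noise, size=n)
    ids = [f"s{i}" for i in range(n)]
    summaries = pd.DataFrame({"subject_id": ids, "placebo_effect_observed": effect})
    models = pd.DataFrame({
        "subject_id": ids, "model": "bayes", "sigma_prior": sigma_p, "sigma_like": sigma_l,
    })
    return summaries, models


def test_regression_recovers_exact_construction(rng):
    summaries, models = _regression_tables(rng, noise=0.0)
    res = pb.regress_placebo_on_sigmas(summaries, models)
    assert res.params["intercept"] == pytest.approx(15.005, abs=1e-9)
    assert res.params["sigma_prior"] == pytest.approx(-0.883, abs=1e-9)
    assert res.params["sigma_like"] == pytest.approx(0.562, abs=1e-9)
    assert res.r_squared == pytest.approx(1.0, abs=1e-9)


def test_regression_matches_normal_equations_oracle(rng):
    summaries, models = _regression_tables(rng, noise=5.0)
    res = pb.regress_placebo_on_sigmas(summaries, models)
    X = np.column_stack([
        np.ones(len(models)), models.sigma_prior.to_numpy(), models.sigma_like.to_numpy(),
    ])
    y = summaries.placebo_effect_observed.to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.params["intercept"] == pytest.approx(beta[0], abs=1e-9)
    assert res.params["sigma_prior"] == pytest.approx(beta[1], abs=1e-9)
    assert res.params["sigma_like"] == pytest.approx(beta[2], abs=1e-9)
    assert res.adj_r_squared <= res.r_squared <= 1.0


def test_regression_rejects_collinear_predictors(rng):
    summaries, models = _regression_tables(rng, noise=1.0)
    models["sigma_like"] = 2.0 * models["sigma_prior"]
    with pytest.raises(ParameterError):
        pb.regress_placebo_on_sigmas(summaries, models)


def test_synthetic_cohort_group_effects_and_correlations(small_chain):
    """Constant-temperature conditioning (HTP) should produce the larger mean
    placebo effect, and both model-derived quantities should track it."""
    trials, _, _, models, _ = small_chain
    summaries = pb.apply_subsample_cutoffs(pb.summarize_cohort(trials, models))
    by_group = summaries.groupby("group").placebo_effect_observed.mean()
    assert by_group["HTP"] > by_group["LTP"]
    merged = summaries.merge(
        models[models.model == "bayes"][["subject_id", "w_prior"]], on="subject_id"
    )
    r_pred, _ = pb.pearson_correlation(
        merged.placebo_effect_predicted, merged.placebo_effect_observed
    )
    r_w, _ = pb.pearson_correlation(merged.w_prior, merged.placebo_effect_observed)
    assert r_pred > 0
    assert r_w > 0
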