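import hashlib
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import placebayes as pb
from placebayes.errors import ParameterError


def test_psychometric_midpoint_maps_to_vas_50():
    psy = pb.make_psychometric(45.0, 38.5)
    assert psy(45.0) == pytest.approx(50.0)


def test_psychometric_inverse_identity():
    psy = pb.make_psychometric(44.7, 33.0)
    for vas in (10.0, 30.0, 50.0, 70.0, 95.0):
        assert psy(psy.invert(vas)) == pytest.approx(vas, abs=1e-9)


def test_psychometric_monotone_increasing():
    psy = pb.make_psychometric(45.0, 40.0)
    temps = np.linspace(40, 50, 200)
    assert np.all(np.diff(psy(temps)) > 0)


def test_calibration_span_against_root_finding_oracle():
    """Slope 38.5 VAS/degC gives a VAS30->VAS70 temperature span of ~1.1 degC
    (the group-mean calibration span); verified by numeric inversion."""
    psy = pb.make_psychometric(45.0, 38.5)

    def numeric_invert(target):
        return optimize.brentq(lambda t: psy(t) - target, 30.0, 60.0, xtol=1e-12)

    t30, t70 = numeric_invert(30.0), numeric_invert(70.0)
    assert psy.invert(30.0) == pytest.approx(t30, abs=1e-9)
    assert psy.invert(70.0) == pytest.approx(t70, abs=1e-9)
    assert t70 - t30 == pytest.approx(1.1, abs=0.01)


def test_non_positive_slope_rejected():
    with pytest.raises(ParameterError):
        pb.make_psychometric(45.0, 0.0)


def test_offset_schedule_matches_design():
    sched = pb.ltp_offset_schedule(12, 0.55, 0.8)
    assert np.sum(sched) == pytest.approx(0.0, abs=1e-12)  # exact +/- pairing
    assert np.std(sched, ddof=1) == pytest.approx(0.55, abs=1e-6)
    assert np.max(np.abs(sched)) <= 0.8 + 1e-12
    assert sorted(sched) == sorted(-x for x in sched)


def test_offset_schedule_degenerate_and_infeasible():
    assert np.all(pb.ltp_offset_schedule(12, 0.0, 0.8) == 0.0)
    with pytest.raises(ParameterError):
        pb.ltp_offset_schedule(12, 0.9, 0.8)
    with pytest.raises(ParameterError):
        pb.ltp_offset_schedule(11, 0.5, 0.8)


def test_offset_schedule_shuffle_is_seeded():
    a = pb.ltp_offset_schedule(12, 0.55, 0.8, rng=np.random.default_rng(3))
    b = pb.ltp_offset_schedule(12, 0.55, 0.8, rng=np.random.default_rng(3))
    assert np.array_equal(a, b)


def _frame_hash(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def test_simulation_is_deterministic():
    cfg = pb.CohortConfig(seed=99, n_htp=4, n_ltp=4)
    t1, g1 = pb.simulate_cohort(cfg)
    t2, g2 = pb.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(t1, t2)
    assert _frame_hash(t1) == _frame_hash(t2)
    assert _frame_hash(g1) == _frame_hash(g2)


def test_cohort_structure_and_bounds(small_cohort):
    cfg, trials, truth = small_cohort
    assert len(truth) == cfg.n_htp + cfg.n_ltp
    counts = trials.groupby(["subject_id", "phase", "condition"]).size()
    assert (counts == cfg.trials_per_condition).all()
    assert trials.vas.between(0, 100).all()
    # HTP conditioning-placebo temperature constant; LTP jittered
    cp = trials[(trials.phase == "conditioning") & (trials.condition == "placebo")]
    temp_spread = cp.groupby("subject_id").temperature_c.agg(np.ptp)
    groups = truth.set_index("subject_id").group
    assert (temp_spread[groups == "HTP"] == 0).all()
    assert (temp_spread[groups == "LTP"] > 0).all()
    # test phase: identical constant temperature in both conditions
    test = trials[trials.phase == "test"]
    assert (test.groupby(["subject_id", "condition"]).temperature_c.agg(np.ptp) == 0).all()
    assert (test.groupby("subject_id").temperature_c.agg(np.ptp) == 0).all()


def test_large_cohort_anchored_at_vas_30():
    """Law-of-large-numbers check: conditioning-placebo ratings centre on the
    VAS-30 anchor across many subjects."""
    cfg = pb.CohortConfig(seed=5, n_htp=200, n_ltp=200)
    trials, _ = pb.simulate_cohort(cfg)
    cp = trials[(trials.phase == "conditioning") & (trials.condition == "placebo")]
    assert abs(cp.groupby("subject_id").vas.mean().mean() - 30.0) < 1.0
    # manipulation fidelity: temperature jitter inflates LTP rating variability
    sds = cp.groupby(["group", "subject_id"]).vas.std()
    assert sds["LTP"].mean() > sds["HTP"].mean() + 2.0


def test_zero_jitter_makes_groups_exchangeable():
    cfg = pb.CohortConfig(seed=6, n_htp=100, n_ltp=100, ltp_temp_sd=0.0)
    trials, _ = pb.simulate_cohort(cfg)
    cp = trials[(trials.phase == "conditioning") & (trials.condition == "placebo")]
    sds = cp.groupby(["group", "subject_id"]).vas.std()
    assert abs(sds["LTP"].mean() - sds["HTP"].mean()) < 1.0


def test_clip_policy_respects_bounds():
    cfg = pb.CohortConfig(seed=8, n_htp=4, n_ltp=4, truncation_policy="clip")
    trials, _ = pb.simulate_cohort(cfg)
    assert trials.vas.between(0, 100).all()


def test_fraction_bayes_controls_generating_models():
    cfg = pb.CohortConfig(seed=9, n_htp=10, n_ltp=10, fraction_bayes_subjects=0.5)
    _, truth = pb.simulate_cohort(cfg)
    assert (truth.generating_model == "bayes").sum() == 10
    preset = pb.heterogeneous_cohort_config(seed=9, n_htp=10, n_ltp=10)
    _, truth = pb.simulate_cohort(preset)
    assert (truth.generating_model == "bayes").sum() == 18


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_htp": 0},
        {"vas_cond_placebo_mean": 130.0},
        {"fraction_bayes_subjects": 1.5},
        {"rating_noise_sd_range": (0.0, 5.0)},
        {"truncation_policy": "wrap"},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ParameterError):
        pb.CohortConfig(seed=1, **kwargs)
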