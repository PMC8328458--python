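"""Precision correction, c/prevalence conversion, curve calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbcurves import simulate as sim
from pbcurves.calibration import (
    CalibrationSpec,
    c_from_prevalence,
    calibrate_curve,
    correct_precision,
    fpr_from_precision,
    prevalence_from_c,
)
from pbcurves.curves import (
    ScoredSet,
    auc,
    ordinate_difference,
    pr_curve,
    roc_curve,
    sweep_confusions,
)
from pbcurves.errors import CountMismatchError, InconsistentCountsError
from pbcurves.metrics import hidden_truth_metrics


@pytest.mark.parametrize(
    "prev, n1, n0, expected",
    [
        (0.1638, 1000, 5000, 0.5498),
        (0.2292, 2000, 10000, 0.4660),
        (1.0, 700, 700, 0.5),
    ],
)
def test_case_control_c_from_prevalence(prev, n1, n0, expected):
    c = c_from_prevalence(prev, n1=n1, n0=n0, scenario="case_control")
    assert round(c, 4) == expected


def test_single_training_set_c_from_prevalence():
    c = c_from_prevalence(0.25, n1=500, t=4000, scenario="single")
    assert c == pytest.approx(0.5)
    with pytest.raises(InconsistentCountsError):
        # more labeled presences than presences
        c_from_prevalence(0.05, n1=500, t=4000, scenario="single")


def test_case_control_prevalence_from_c():
    prev = prevalence_from_c(0.5664, n1=1000, n0=5000, scenario="case_control")
    assert round(prev, 4) == 0.1531
    assert prevalence_from_c(1.0, n1=700, n0=700, scenario="case_control") == 0.0


@given(
    prev=st.floats(min_value=0.05, max_value=1.0),
    n1=st.integers(50, 5000),
    n0=st.integers(50, 20000),
    scenario=st.sampled_from(["case_control", "single_training_set"]),
)
@settings(max_examples=100, derandomize=True)
def test_c_prevalence_round_trip(prev, n1, n0, scenario):
    try:
        c = c_from_prevalence(prev, n1=n1, n0=n0, scenario=scenario)
    except InconsistentCountsError:
        return  # counts incompatible with this prevalence
    back = prevalence_from_c(c, n1=n1, n0=n0, scenario=scenario)
    assert back == pytest.approx(prev, rel=1e-9)


def test_calibration_spec_derives_missing_quantity():
    spec = CalibrationSpec(scenario="case_control", n1=1000, n0=5000, prevalence=0.1638)
    assert spec.c == pytest.approx(0.5498, abs=5e-5)
    spec = CalibrationSpec(scenario="case_control", n1=1000, n0=5000, c=0.5664)
    assert spec.prevalence == pytest.approx(0.1531, abs=5e-5)


def test_calibration_spec_validation():
    with pytest.raises(InconsistentCountsError):
        CalibrationSpec(scenario="case_control", n1=1000, n0=5000)
    with pytest.raises(InconsistentCountsError):
        CalibrationSpec(
            scenario="case_control", n1=1000, n0=5000, c=0.5, prevalence=0.2
        )
    with pytest.raises(InconsistentCountsError):  # c = 0 rejected outright
        CalibrationSpec(scenario="case_control", n1=1000, n0=5000, c=0.0)


@pytest.mark.parametrize("scenario", ["case_control", "single_training_set"])
def test_correct_precision_fixed_points(scenario):
    spec = CalibrationSpec(scenario=scenario, n1=100, n0=500, c=0.44)
    assert correct_precision(0.44, spec).value == pytest.approx(1.0)
    assert correct_precision(0.0, spec).value == 0.0


def test_correct_precision_divergence_clips_with_flag():
    spec = CalibrationSpec(scenario="case_control", n1=100, n0=500, c=0.6)
    value, clipped = correct_precision(1.0, spec)
    assert value == 1.0 and clipped
    value, clipped = correct_precision(0.9, spec)  # raw would exceed 1
    assert value == 1.0 and clipped


@pytest.mark.parametrize("scenario", ["case_control", "single_training_set"])
def test_corrected_precision_monotone_in_naive_precision(scenario):
    for c in (0.2, 0.5, 0.8, 1.0):
        spec = CalibrationSpec(scenario=scenario, n1=100, n0=900, c=c)
        grid = np.linspace(0, 0.999, 200)
        vals = [correct_precision(p, spec).value for p in grid]
        assert np.all(np.diff(vals) >= 0)


def test_fpr_from_precision_examples():
    assert fpr_from_precision(1.0, 0.7, 0.3).value == 0.0
    assert fpr_from_precision(0.5, 0.5, 0.5).value == pytest.approx(0.5)


def test_calibrated_curve_equals_pa_curve_when_everything_labeled(rng):
    """With c = 1 in the single-training-set scenario there are no
    unlabeled presences, so the calibrated curve must coincide with the
    PA curve built by treating unlabeled as absent."""
    scores = rng.random(400)
    truth = rng.random(400) < 0.3
    truth[:2] = [True, False]
    pb_set = ScoredSet(
        scores=scores, labels=truth, mode="pb",
        scenario="single_training_set", true_labels=truth,
    )
    pa_set = ScoredSet(scores=scores, labels=truth, mode="pa")
    spec = CalibrationSpec(
        scenario="single_training_set",
        n1=pb_set.n_positive, n0=pb_set.n_negative, c=1.0,
    )
    for build in (roc_curve, pr_curve):
        pb = calibrate_curve(build(pb_set, mode="po"), spec)
        pa = build(pa_set, mode="pa")
        assert auc(pb) == pytest.approx(auc(pa), abs=1e-12)
        assert ordinate_difference(pa, pb) < 1e-12


def test_corrected_precision_tracks_hidden_truth(spec1_world):
    """With the realized c, the corrected precision recovers the
    hidden-truth precision up to sampling noise at each threshold."""
    _, _, real = spec1_world
    data = sim.sample_case_control(real, 1000, 5.0, seed=23)
    spec = CalibrationSpec(
        scenario="case_control", n1=1000, n0=5000, c=data.meta["realized_c"]
    )
    diffs = []
    for thr, conf in sweep_confusions(data):
        if conf.m2 + conf.m3 < 25:  # skip noise-dominated tiny counts
            continue
        truth = hidden_truth_metrics(conf, "case_control")
        corrected = correct_precision(conf.m1 / conf.k1, spec).value
        diffs.append(abs(corrected - truth.precision))
    assert np.mean(diffs) < 0.05
    assert np.median(diffs) < 0.03


def test_overestimated_c_lowers_both_calibrated_curves(spec1_world):
    _, _, real = spec1_world
    data = sim.sample_case_control(real, 1000, 5.0, seed=29)
    c0 = data.meta["realized_c"]
    naive_roc = roc_curve(data, mode="po")
    naive_pr = pr_curve(data, mode="po")
    def aucs(c):
        spec = CalibrationSpec(scenario="case_control", n1=1000, n0=5000, c=c)
        return (
            auc(calibrate_curve(naive_roc, spec)),
            auc(calibrate_curve(naive_pr, spec)),
        )
    roc_true, pr_true = aucs(c0)
    roc_hi, pr_hi = aucs(min(1.1 * c0, 1.0))
    roc_lo, pr_lo = aucs(0.9 * c0)
    assert roc_hi < roc_true < roc_lo
    assert pr_hi < pr_true < pr_lo


def test_calibration_count_mismatch_rejected(spec1_world):
    _, _, real = spec1_world
    data = sim.sample_case_control(real, 200, 5.0, seed=31)
    naive = pr_curve(data, mode="po")
    spec = CalibrationSpec(scenario="case_control", n1=999, n0=1000, c=0.5)
    with pytest.raises(CountMismatchError):
        calibrate_curve(naive, spec)
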