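"""Threshold sweeps, curve construction and AUC."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from pbcurves import simulate as sim
from pbcurves.curves import (
    Curve,
    CurvePoint,
    ScoredSet,
    auc,
    ordinate_difference,
    pa_oracle_set,
    pr_curve,
    roc_curve,
    sweep_confusions,
)
from pbcurves.errors import DegenerateCurveError
from pbcurves.metrics import hidden_truth_metrics


def test_sweep_two_record_example():
    data = ScoredSet(scores=[0.9, 0.1], labels=[True, False])
    out = list(sweep_confusions(data))
    assert [t for t, _ in out] == [0.9, 0.1]
    assert (out[0][1].tp, out[0][1].fp) == (1, 0)
    assert (out[1][1].tp, out[1][1].fp) == (1, 1)


def test_sweep_one_threshold_per_distinct_score(rng):
    scores = rng.permutation(np.linspace(0, 1, 40))
    labels = rng.random(40) < 0.5
    labels[0], labels[1] = True, False
    data = ScoredSet(scores=scores, labels=labels)
    assert len(list(sweep_confusions(data))) == 40
    # ties collapse into blocks
    tied = ScoredSet(scores=[0.5, 0.5, 0.2, 0.2], labels=[1, 0, 1, 0])
    assert len(list(sweep_confusions(tied))) == 2


def test_sweep_matches_brute_force_recount(rng):
    scores = rng.choice(np.round(rng.random(60), 2), size=200)
    labels = rng.random(200) < 0.4
    labels[:2] = [True, False]
    data = ScoredSet(scores=scores, labels=labels)
    for thr, conf in sweep_confusions(data):
        pred = scores >= thr
        assert conf.tp == int((pred & labels).sum())
        assert conf.fp == int((pred & ~labels).sum())
        assert conf.fn == int((~pred & labels).sum())
        assert conf.tn == int((~pred & ~labels).sum())


def test_roc_perfect_separation_passes_through_corner():
    data = ScoredSet(scores=[0.9, 0.8, 0.2, 0.1], labels=[1, 1, 0, 0])
    curve = roc_curve(data)
    assert any(p.x == 0.0 and p.y == 1.0 for p in curve.points)
    assert auc(curve) == pytest.approx(1.0)


def test_roc_constant_scores_is_diagonal():
    data = ScoredSet(scores=[0.5] * 6, labels=[1, 1, 0, 0, 0, 1])
    curve = roc_curve(data)
    interior = [p for p in curve.points if np.isfinite(p.threshold)]
    assert len(interior) == 1 and (interior[0].x, interior[0].y) == (1.0, 1.0)
    assert auc(curve) == pytest.approx(0.5)


def test_pr_perfect_separation_reaches_full_precision():
    data = ScoredSet(scores=[0.9, 0.8, 0.2, 0.1], labels=[1, 1, 0, 0])
    curve = pr_curve(data)
    assert max(p.y for p in curve.points) == pytest.approx(1.0)


def test_pr_lowest_threshold_precision_is_positive_fraction():
    data = ScoredSet(scores=[0.7, 0.6, 0.5, 0.4], labels=[1, 0, 1, 0])
    last = pr_curve(data).points[-1]
    assert last.x == 1.0 and last.y == pytest.approx(0.5)


def test_roc_monotone_in_threshold(rng):
    data = ScoredSet(scores=rng.random(300), labels=rng.random(300) < 0.3)
    pts = [p for p in roc_curve(data).points if np.isfinite(p.threshold)]
    tpr = np.array([p.y for p in pts])
    fpr = np.array([p.x for p in pts])
    assert np.all(np.diff(tpr) >= 0)
    assert np.all(np.diff(fpr) >= 0)


def test_random_scores_give_chance_level_auc(rng):
    n = 500
    data = ScoredSet(scores=rng.random(n), labels=rng.random(n) < 0.5)
    se = np.sqrt(1 / (12 * data.n_positive) + 1 / (12 * data.n_negative))
    assert abs(auc(roc_curve(data)) - 0.5) < 3 * se


def test_roc_auc_agrees_with_rank_statistic_oracles(rng):
    scores = np.round(rng.random(400), 2)  # ties on purpose
    labels = rng.random(400) < 0.35
    labels[:2] = [True, False]
    data = ScoredSet(scores=scores, labels=labels)
    ours = auc(roc_curve(data))
    assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-9)
    u = mannwhitneyu(scores[labels], scores[~labels]).statistic
    assert ours == pytest.approx(u / (labels.sum() * (~labels).sum()), abs=1e-9)


def test_auc_integration_schemes_differ_only_for_pr():
    pts = [CurvePoint(np.inf, 0.0, 1.0), CurvePoint(1.0, 0.5, 1.0),
           CurvePoint(0.5, 1.0, 0.5)]
    curve = Curve(kind="pr", provenance="PA", points=pts)
    assert auc(curve, pr_integration="trapezoid") == pytest.approx(0.875)
    assert auc(curve, pr_integration="step") == pytest.approx(0.75)
    with pytest.raises(ValueError):
        auc(curve, pr_integration="simpson")


def test_degenerate_zero_span_curve_rejected():
    pts = [CurvePoint(1.0, 0.3, 0.5), CurvePoint(0.5, 0.3, 0.9)]
    with pytest.raises(DegenerateCurveError):
        auc(Curve(kind="roc", provenance="PA", points=pts))


def test_ordinate_difference_zero_for_identical_curves(rng):
    data = ScoredSet(scores=rng.random(100), labels=rng.random(100) < 0.4)
    a, b = roc_curve(data), roc_curve(data)
    assert ordinate_difference(a, b) == 0.0


def test_naive_fpr_never_below_true_fpr(spec1_world):
    """Treating background as absence inflates FPR at every threshold
    for a model that outranks random (some background sites are in fact
    presences the model correctly ranks high)."""
    _, _, real = spec1_world
    data = sim.sample_case_control(real, 500, 5.0, seed=11)
    for thr, conf in sweep_confusions(data):
        fpr_naive = (conf.k1 - conf.m1) / conf.n0
        truth = hidden_truth_metrics(conf, "case_control")
        fpr_true = (
            truth.predicted_positive_fraction
            * (1 - truth.precision)
            / (1 - truth.prevalence)
            if conf.k1 > conf.m1
            else 0.0
        )
        assert fpr_naive >= fpr_true - 1e-12


def test_naive_precision_never_above_true_precision(spec1_world):
    """p' = p/[p + (1-c)/c] <= p at every threshold whenever c <= 1/2
    (then (1-c)/c >= 1); above c = 1/2 the bound can fail at small p."""
    _, _, real = spec1_world
    data = sim.sample_case_control(real, 1000, 10.0, seed=13)
    assert data.meta["realized_c"] <= 0.5
    for thr, conf in sweep_confusions(data):
        if conf.m2 + conf.m3 < 25:  # tiny-count noise breaks the bound
            continue
        p_naive = conf.m1 / conf.k1
        truth = hidden_truth_metrics(conf, "case_control")
        assert p_naive <= truth.precision + 0.02


def test_pa_oracle_uses_background_margin_under_case_control(spec1_world):
    _, _, real = spec1_world
    data = sim.sample_case_control(real, 200, 5.0, seed=17)
    oracle = pa_oracle_set(data)
    assert len(oracle) == data.n_negative
    assert oracle.n_positive == int(data.true_labels[~data.labels].sum())


def test_scored_set_validation():
    with pytest.raises(ValueError):
        ScoredSet(scores=[0.1, 0.2], labels=[True, True])
    with pytest.raises(ValueError):
        ScoredSet(scores=[np.nan, 0.2], labels=[True, False])
    with pytest.raises(ValueError):
        ScoredSet(scores=[0.1, 0.2], labels=[True, False], mode="pb")
    with pytest.raises(ValueError):  # labeled record marked true absence
        ScoredSet(
            scores=[0.1, 0.2], labels=[True, False], mode="pb",
            scenario="case_control", true_labels=[False, False],
        )
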