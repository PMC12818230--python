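"""Metrics against brute-force oracles, split allocation arithmetic,
matched-specificity thresholds, and bootstrap behavior."""

import numpy as np
import pytest

from omipipe import (
    EvalConfig,
    InputError,
    SplitConfig,
    bootstrap_ci,
    bootstrap_difference,
    confusion_metrics,
    match_specificity_threshold,
    roc_auc,
    stratified_split,
    subgroup_eval,
)
from omipipe.evaluation import evaluate_binary, evaluate_model


# -- stratified split -------------------------------------------------------

def test_split_sizes_match_integer_allocation_oracle():
    labels = np.zeros(24511, dtype=int)
    labels[:467] = 1
    assignment = stratified_split(labels, SplitConfig(seed=1))
    sizes = {s: int(np.sum(assignment == s)) for s in ("train", "tune", "validate")}
    assert sum(sizes.values()) == 24511
    assert sizes["train"] in (12255, 12256)
    assert abs(sizes["tune"] - 6128) <= 1
    assert abs(sizes["validate"] - 6128) <= 1
    # per-split OMI proportion within one patient of exact stratification
    for s in ("train", "tune", "validate"):
        n_omi = int(np.sum(labels[assignment == s]))
        expected = 467 * sizes[s] / 24511
        assert abs(n_omi - expected) <= 1


def test_split_is_seed_reproducible_and_exhaustive():
    labels = np.random.default_rng(0).integers(0, 2, size=400)
    a = stratified_split(labels, SplitConfig(seed=7))
    b = stratified_split(labels, SplitConfig(seed=7))
    assert np.array_equal(a, b)
    c = stratified_split(labels, SplitConfig(seed=8))
    assert not np.array_equal(a, c)
    assert set(a) == {"train", "tune", "validate"}


def test_split_fractions_must_sum_to_one():
    with pytest.raises(InputError):
        SplitConfig(fractions=(0.5, 0.3, 0.3))


# -- confusion metrics ------------------------------------------------------

def test_confusion_metrics_hand_computed():
    # 467 positives of which 107 detected; 24044 negatives with 506 false alarms
    labels = np.concatenate([np.ones(467), np.zeros(24044)]).astype(bool)
    pred = np.concatenate(
        [np.arange(467) < 107, np.arange(24044) < 506]
    ).astype(bool)
    cm = confusion_metrics(pred, labels)
    assert cm.sensitivity == pytest.approx(107 / 467)
    assert round(100 * cm.sensitivity, 1) == 22.9
    assert cm.specificity == pytest.approx((24044 - 506) / 24044)
    assert cm.ppv == pytest.approx(107 / 613)


def test_confusion_metrics_degenerate_cases():
    perfect = confusion_metrics([True, False], [True, False])
    assert (
        perfect.sensitivity,
        perfect.specificity,
        perfect.ppv,
        perfect.npv,
    ) == (1, 1, 1, 1)
    none_pred = confusion_metrics([False, False], [True, False])
    assert none_pred.ppv is None
    assert none_pred.sensitivity == 0
    with pytest.raises(InputError):
        confusion_metrics([True], [True, False])


# -- AUC --------------------------------------------------------------------

def _auc_brute_force(scores, labels):
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = wins = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                wins += 1
            elif p == q:
                wins += 0.5
    return wins / total


def test_auc_equals_pair_counting_on_hand_listed_points():
    scores = [0.1, 0.4, 0.35, 0.8, 0.35, 0.9]
    labels = [0, 0, 1, 1, 0, 1]
    assert roc_auc(scores, labels) == pytest.approx(
        _auc_brute_force(scores, labels)
    )


def test_auc_pair_counting_with_ties_randomized():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = int(rng.integers(5, 40))
        scores = rng.integers(0, 5, size=n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_brute_force(scores, labels)
        )


def test_auc_extremes_and_null():
    assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    rng = np.random.default_rng(4)
    scores = rng.random(10_000)
    labels = rng.integers(0, 2, size=10_000)
    assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)
    with pytest.raises(InputError):
        roc_auc([0.1, 0.2], [1, 1])


# -- matched-specificity threshold -----------------------------------------

def _threshold_oracle(scores, labels, target):
    """Exhaustive scan over candidate thresholds."""
    scores, labels = np.asarray(scores, float), np.asarray(labels, bool)
    neg = scores[~labels]
    best = None
    for t in sorted(set(scores)) + [np.nextafter(scores.max(), np.inf)]:
        spec = np.mean(neg < t)
        if spec >= target and best is None:
            best = t
    return best


def test_threshold_matches_exhaustive_scan_oracle():
    rng = np.random.default_rng(5)
    scores = np.round(rng.random(30), 2)
    labels = rng.integers(0, 2, size=30).astype(bool)
    labels[:2] = [True, False]
    for target in (0.5, 0.8, 0.9, 1.0):
        t, spec = match_specificity_threshold(
            scores, labels, target_specificity=target
        )
        assert t == pytest.approx(_threshold_oracle(scores, labels, target))
        assert spec >= target


def test_threshold_for_perfect_comparator_exceeds_all_negatives():
    scores = np.array([0.1, 0.2, 0.3, 0.9, 0.95])
    labels = np.array([0, 0, 0, 1, 1], dtype=bool)
    verdicts = np.zeros(5, dtype=bool)  # comparator never fires: spec 1.0
    t, spec = match_specificity_threshold(scores, labels, verdicts)
    assert t > 0.3
    assert spec == 1.0


def test_threshold_monotone_in_target():
    rng = np.random.default_rng(6)
    scores = rng.random(200)
    labels = rng.random(200) < 0.3
    prev = -np.inf
    for target in np.linspace(0.1, 1.0, 10):
        t, _ = match_specificity_threshold(
            scores, labels, target_specificity=float(target)
        )
        assert t >= prev
        prev = t


def test_threshold_requires_negatives():
    with pytest.raises(InputError):
        match_specificity_threshold(
            np.array([0.5]), np.array([True]), target_specificity=0.9
        )


# -- bootstrap --------------------------------------------------------------

def test_bootstrap_constant_metric_zero_width():
    labels = np.ones(50, dtype=bool)

    def sens(idx):
        return confusion_metrics(np.ones(len(idx), bool), labels[idx]).sensitivity

    ci = bootstrap_ci(sens, 50, EvalConfig(n_bootstrap=100, seed=1))
    assert ci.point == ci.lo == ci.hi == 1.0


def test_bootstrap_seed_reproducible():
    rng = np.random.default_rng(7)
    x = rng.random(100)

    def mean(idx):
        return float(np.mean(x[idx]))

    a = bootstrap_ci(mean, 100, EvalConfig(n_bootstrap=200, seed=3))
    b = bootstrap_ci(mean, 100, EvalConfig(n_bootstrap=200, seed=3))
    assert (a.lo, a.hi) == (b.lo, b.hi)


def test_bootstrap_difference_self_is_zero():
    rng = np.random.default_rng(8)
    x = rng.random(60)

    def mean(idx):
        return float(np.mean(x[idx]))

    ci = bootstrap_difference(mean, mean, 60, EvalConfig(n_bootstrap=100, seed=2))
    assert ci.point == 0.0 and ci.lo == 0.0 and ci.hi == 0.0


def test_bootstrap_difference_point_is_difference_of_points():
    rng = np.random.default_rng(9)
    x, z = rng.random(80), rng.random(80)

    def mx(idx):
        return float(np.mean(x[idx]))

    def mz(idx):
        return float(np.mean(z[idx]))

    ci = bootstrap_difference(mx, mz, 80, EvalConfig(n_bootstrap=50, seed=4))
    assert ci.point == pytest.approx(np.mean(x) - np.mean(z))


def test_dominating_model_difference_excludes_zero():
    labels = np.random.default_rng(10).random(300) < 0.3
    good = labels.astype(float) * 0.8 + 0.1  # near-perfect scores
    bad = np.random.default_rng(11).random(300)

    def sens_of(scores):
        pred = scores >= 0.5

        def fn(idx):
            return confusion_metrics(pred[idx], labels[idx]).sensitivity

        return fn

    ci = bootstrap_difference(
        sens_of(good), sens_of(bad), 300, EvalConfig(n_bootstrap=200, seed=5)
    )
    assert ci.lo > 0


def test_undefined_resamples_are_counted():
    # a single positive: many resamples lack positives entirely
    labels = np.zeros(20, dtype=bool)
    labels[0] = True
    pred = labels.copy()

    def sens(idx):
        return confusion_metrics(pred[idx], labels[idx]).sensitivity

    ci = bootstrap_ci(sens, 20, EvalConfig(n_bootstrap=200, seed=6))
    assert ci.n_undefined_resamples > 0


# -- subgroup evaluation ----------------------------------------------------

def test_subgroups_partition_true_positive_count():
    rng = np.random.default_rng(12)
    labels = rng.random(400) < 0.2
    scores = np.clip(labels * 0.6 + rng.random(400) * 0.4, 0, 1)
    female = rng.random(400) < 0.5
    thr = 0.5
    reports = subgroup_eval(
        scores,
        labels,
        thr,
        {"female": female, "male": ~female},
        EvalConfig(n_bootstrap=10, seed=1),
    )
    tp_total = int(np.sum((scores >= thr) & labels))
    tp_f = int(np.sum((scores >= thr) & labels & female))
    tp_m = int(np.sum((scores >= thr) & labels & ~female))
    assert tp_f + tp_m == tp_total
    # subgroup sensitivities recompute on filtered cohorts, same threshold
    assert reports["female"].sensitivity.point == pytest.approx(
        tp_f / max(1, int(np.sum(labels & female)))
    )


def test_binary_comparator_report_has_no_auc():
    labels = np.array([1, 0, 1, 0, 1, 0] * 10, dtype=bool)
    pred = np.array([1, 0, 0, 0, 1, 1] * 10, dtype=bool)
    rep = evaluate_binary(pred, labels, EvalConfig(n_bootstrap=20, seed=1))
    assert rep.auc is None
    assert rep.sensitivity.point == pytest.approx(2 / 3)
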