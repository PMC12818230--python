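"""Cohort splitting, diagnostic metrics, matched-specificity thresholds,
and bootstrap confidence intervals.

The evaluation protocol mirrors a matched-specificity comparison: the risk
model's decision threshold is chosen so that its specificity on the tuning
set is at least that of the rule-based comparator, making sensitivities
directly comparable.  Confidence intervals are percentile bootstrap over
patient resamples (B = 1000, 95% by default); paired model comparisons
bootstrap the per-resample difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .types import InputError

SPLIT_NAMES = ("train", "tune", "validate")


@dataclass
class SplitConfig:
    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InputError("split fractions must sum to 1")


@dataclass
class EvalConfig:
    n_bootstrap: int = 1000
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise InputError("n_bootstrap must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise InputError("ci_level must be in (0, 1)")


@dataclass
class MetricCI:
    point: Optional[float]
    lo: Optional[float] = None
    hi: Optional[float] = None
    n_undefined_resamples: int = 0


@dataclass
class MetricsReport:
    cohort: str
    n: int
    threshold: Optional[float] = None
    auc: Optional[MetricCI] = None
    sensitivity: Optional[MetricCI] = None
    specificity: Optional[MetricCI] = None
    ppv: Optional[MetricCI] = None
    npv: Optional[MetricCI] = None


def stratified_split(
    labels: Sequence[int] | np.ndarray, config: SplitConfig = SplitConfig()
) -> np.ndarray:
    """Assign each patient to train/tune/validate, stratified on the outcome.

    Within each stratum the allocation is proportional with the remainder
    distributed by largest fractional part (ties broken in split order), so
    split sizes are within one patient of the exact fractions.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(config.seed)
    assignment = np.empty(labels.shape[0], dtype=object)
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        rng.shuffle(idx)
        n = idx.size
        exact = np.array([f * n for f in config.fractions])
        base = np.floor(exact).astype(int)
        remainder = n - base.sum()
        order = np.argsort(-(exact - base), kind="stable")
        for j in order[:remainder]:
            base[j] += 1
        bounds = np.cumsum(base)
        assignment[idx[: bounds[0]]] = "train"
        assignment[idx[bounds[0] : bounds[1]]] = "tune"
        assignment[idx[bounds[1] :]] = "validate"
    return assignment


@dataclass
class ConfusionMetrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]


def confusion_metrics(
    predictions: Sequence[bool] | np.ndarray, labels: Sequence[bool] | np.ndarray
) -> ConfusionMetrics:
    """Sensitivity, specificity, PPV, NPV; undefined ratios are None."""
    pred = np.asarray(predictions, dtype=bool)
    lab = np.asarray(labels, dtype=bool)
    if pred.shape != lab.shape:
        raise InputError("predictions and labels length mismatch")
    tp = int(np.sum(pred & lab))
    fp = int(np.sum(pred & ~lab))
    fn = int(np.sum(~pred & lab))
    tn = int(np.sum(~pred & ~lab))

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return ConfusionMetrics(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
    )


def roc_auc(scores: Sequence[float] | np.ndarray, labels) -> float:
    """AUC = Mann–Whitney probability with ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise InputError("roc_auc requires both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def match_specificity_threshold(
    tuning_scores: np.ndarray,
    tuning_labels: np.ndarray,
    comparator_verdicts: Optional[np.ndarray] = None,
    target_specificity: Optional[float] = None,
) -> tuple[float, float]:
    """Smallest threshold whose tuning specificity reaches the target.

    The target defaults to the comparator's specificity on the tuning-set
    negatives.  A prediction is positive when score >= threshold.  Returns
    (threshold, achieved specificity).
    """
    scores = np.asarray(tuning_scores, dtype=float)
    labels = np.asarray(tuning_labels, dtype=bool)
    neg = scores[~labels]
    if neg.size == 0:
        raise InputError("no negatives on the tuning set")
    if target_specificity is None:
        if comparator_verdicts is None:
            raise InputError("need comparator verdicts or an explicit target")
        verdicts = np.asarray(comparator_verdicts, dtype=bool)
        target_specificity = float(np.mean(~verdicts[~labels]))
    candidates = np.unique(scores)
    candidates = np.append(candidates, np.nextafter(candidates[-1], np.inf))
    neg_sorted = np.sort(neg)
    for t in candidates:
        spec = np.searchsorted(neg_sorted, t, side="left") / neg.size
        if spec >= target_specificity:
            return float(t), float(spec)
    return float(candidates[-1]), float(
        np.searchsorted(neg_sorted, candidates[-1], side="left") / neg.size
    )


def bootstrap_ci(
    metric_fn: Callable[[np.ndarray], Optional[float]],
    n: int,
    config: EvalConfig = EvalConfig(),
) -> MetricCI:
    """Percentile bootstrap CI of ``metric_fn`` over patient resamples.

    ``metric_fn`` receives an index array into the cohort (the identity
    permutation for the point estimate) and may return None when the metric
    is undefined on a resample; such resamples are skipped and counted.
    """
    if n < 2:
        raise InputError("bootstrap needs n >= 2")
    rng = np.random.default_rng(config.seed)
    point = metric_fn(np.arange(n))
    values = []
    undefined = 0
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        v = metric_fn(idx)
        if v is None or not np.isfinite(v):
            undefined += 1
        else:
            values.append(v)
    if not values:
        return MetricCI(point=point, n_undefined_resamples=undefined)
    alpha = 1.0 - config.ci_level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MetricCI(
        point=point, lo=float(lo), hi=float(hi), n_undefined_resamples=undefined
    )


def bootstrap_difference(
    metric_fn_a: Callable[[np.ndarray], Optional[float]],
    metric_fn_b: Callable[[np.ndarray], Optional[float]],
    n: int,
    config: EvalConfig = EvalConfig(),
) -> MetricCI:
    """Percentile CI of the paired difference (a − b) on shared resamples."""
    if n < 2:
        raise InputError("bootstrap needs n >= 2")
    rng = np.random.default_rng(config.seed)
    pa, pb = metric_fn_a(np.arange(n)), metric_fn_b(np.arange(n))
    point = None if pa is None or pb is None else pa - pb
    values = []
    undefined = 0
    for _ in range(config.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        va, vb = metric_fn_a(idx), metric_fn_b(idx)
        if va is None or vb is None:
            undefined += 1
        else:
            values.append(va - vb)
    if not values:
        return MetricCI(point=point, n_undefined_resamples=undefined)
    alpha = 1.0 - config.ci_level
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MetricCI(
        point=point, lo=float(lo), hi=float(hi), n_undefined_resamples=undefined
    )


def evaluate_model(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    config: EvalConfig = EvalConfig(),
    cohort: str = "validation",
    with_auc: bool = True,
) -> MetricsReport:
    """Bootstrap report for a continuous risk score at a fixed threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    pred = scores >= threshold

    def make(metric: str) -> Callable[[np.ndarray], Optional[float]]:
        def fn(idx: np.ndarray) -> Optional[float]:
            cm = confusion_metrics(pred[idx], labels[idx])
            return getattr(cm, metric)

        return fn

    def auc_fn(idx: np.ndarray) -> Optional[float]:
        if len(np.unique(labels[idx])) < 2:
            return None
        return roc_auc(scores[idx], labels[idx])

    report = MetricsReport(cohort=cohort, n=n, threshold=float(threshold))
    if with_auc:
        report.auc = bootstrap_ci(auc_fn, n, config)
    report.sensitivity = bootstrap_ci(make("sensitivity"), n, config)
    report.specificity = bootstrap_ci(make("specificity"), n, config)
    report.ppv = bootstrap_ci(make("ppv"), n, config)
    report.npv = bootstrap_ci(make("npv"), n, config)
    return report


def evaluate_binary(
    predictions: np.ndarray,
    labels: np.ndarray,
    config: EvalConfig = EvalConfig(),
    cohort: str = "validation",
) -> MetricsReport:
    """Bootstrap report for a binary comparator (no AUC: it is only
    meaningful for nonbinary predictions)."""
    pred = np.asarray(predictions, dtype=bool)
    labels = np.asarray(labels, dtype=bool)
    n = labels.size

    def make(metric: str) -> Callable[[np.ndarray], Optional[float]]:
        def fn(idx: np.ndarray) -> Optional[float]:
            return getattr(confusion_metrics(pred[idx], labels[idx]), metric)

        return fn

    report = MetricsReport(cohort=cohort, n=n)
    report.sensitivity = bootstrap_ci(make("sensitivity"), n, config)
    report.specificity = bootstrap_ci(make("specificity"), n, config)
    report.ppv = bootstrap_ci(make("ppv"), n, config)
    report.npv = bootstrap_ci(make("npv"), n, config)
    return report


def subgroup_eval(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    subgroup_masks: dict[str, np.ndarray],
    config: EvalConfig = EvalConfig(),
) -> dict[str, MetricsReport]:
    """Re-evaluate on filtered cohorts with the global threshold unchanged."""
    out: dict[str, MetricsReport] = {}
    for name, mask in subgroup_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            continue
        sub_labels = np.asarray(labels, dtype=bool)[mask]
        out[name] = evaluate_model(
            np.asarray(scores, dtype=float)[mask],
            sub_labels,
            threshold,
            config,
            cohort=name,
            with_auc=len(np.unique(sub_labels)) == 2,
        )
    return out
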