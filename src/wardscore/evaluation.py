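"""Discrimination and threshold metrics with bootstrap confidence intervals.

AUROC is the Mann-Whitney concordance probability (ties count 1/2);
AUPRC is step-wise average precision (sum of delta-recall x precision over
descending score thresholds, ties grouped) — not trapezoidal PR
interpolation, which over-estimates the area.  Threshold metrics use the
positivity rule ``score >= threshold``.  Confidence intervals are
percentile bootstrap over evaluation samples (encounter at a fixed
offset), resampled with replacement at the original size; the reported
location is the bootstrap median, matching how the study summarises its
metrics (median and 95% CI over 1000 resamples).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import Encounter

METRICS = ("AUROC", "AUPRC", "recall", "specificity", "precision", "F1")


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined on the given labels (e.g. one class)."""


def _check(labels, scores) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-d and equal length")
    return labels.astype(int), scores


def auroc(labels, scores) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    labels, scores = _check(labels, scores)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC needs both classes")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Average precision: sum over thresholds of delta-recall x precision."""
    labels, scores = _check(labels, scores)
    if labels.sum() < 1:
        raise UndefinedMetricError("AUPRC needs at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass(frozen=True)
class ThresholdMetrics:
    recall: float
    specificity: float
    precision: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "recall": self.recall,
            "specificity": self.specificity,
            "precision": self.precision,
            "F1": self.f1,
        }


def f1_from(recall: float, precision: float) -> float:
    """Harmonic mean of recall and precision; NaN when undefined."""
    if np.isnan(recall) or np.isnan(precision) or recall + precision == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def threshold_metrics(labels, scores, threshold: float) -> ThresholdMetrics:
    """Recall/specificity/precision/F1 at positivity rule score >= threshold.

    Zero-denominator cases yield NaN (flagged undefined); bootstrap
    aggregation excludes such resamples.
    """
    labels, scores = _check(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    recall = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    precision = tp / (tp + fp) if tp + fp else float("nan")
    return ThresholdMetrics(recall, specificity, precision, f1_from(recall, precision))


@dataclass
class MetricEstimate:
    metric: str
    median: float
    ci_low: float
    ci_high: float
    point: float
    n: int
    n_boot: int
    seed: int
    n_undefined: int = 0
    unreliable: bool = False
    score: str | None = None
    offset: int | None = None
    mode: str | None = None
    lookback: float | None = None
    outcome: str | None = None


def bootstrap(
    metric_fn: Callable[[np.ndarray, np.ndarray], float],
    labels,
    scores,
    n_boot: int = 1000,
    seed: int = 0,
    stratified: bool = False,
    max_redraws: int = 10,
) -> MetricEstimate:
    """Percentile bootstrap (50/2.5/97.5) of ``metric_fn`` over resamples.

    Resampling is with replacement at the original size.  Resamples on
    which the metric is undefined (e.g. single-class) are redrawn up to
    ``max_redraws`` times and then dropped with a count; the estimate is
    flagged unreliable if more than half the resamples are dropped.
    """
    labels, scores = _check(labels, scores)
    n = len(labels)
    rng = np.random.default_rng(seed)
    point = metric_fn(labels, scores)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    vals = []
    n_undefined = 0
    for _ in range(n_boot):
        v = None
        for _ in range(max_redraws):
            if stratified:
                idx = np.concatenate(
                    [rng.choice(pos, size=len(pos)), rng.choice(neg, size=len(neg))]
                )
            else:
                idx = rng.integers(0, n, size=n)
            try:
                v = metric_fn(labels[idx], scores[idx])
            except UndefinedMetricError:
                continue
            if not np.isnan(v):
                break
            v = None
        if v is None:
            n_undefined += 1
        else:
            vals.append(v)
    if not vals:
        raise UndefinedMetricError("metric undefined on every bootstrap resample")
    med, lo, hi = np.percentile(vals, [50.0, 2.5, 97.5])
    return MetricEstimate(
        metric=getattr(metric_fn, "__name__", "metric"),
        median=float(med),
        ci_low=float(lo),
        ci_high=float(hi),
        point=float(point),
        n=n,
        n_boot=n_boot,
        seed=seed,
        n_undefined=n_undefined,
        unreliable=n_undefined > n_boot / 2,
    )


def derive_secondary_labels(
    encounter: Encounter, index_time: datetime
) -> tuple[int, int]:
    """(death within 48 h of index, death-or-ICU-transfer within 48 h).

    The window is half-open below and closed above: (index, index + 48 h].
    The composite adds any ICU interval *starting* in that window.
    """
    end = index_time + timedelta(hours=48)
    death48 = int(
        encounter.death_time is not None and index_time < encounter.death_time <= end
    )
    icu48 = any(index_time < s <= end for s, _ in encounter.icu_intervals)
    return death48, int(death48 or icu48)


def build_eval_samples(
    cohort: pd.DataFrame, encounters: dict[str, Encounter]
) -> pd.DataFrame:
    """Per-encounter outcome labels for every indexed sepsis/control record.

    ``cohort`` needs columns encounter_id, label, index_time.
    """
    rows = []
    for r in cohort.itertuples(index=False):
        if r.label not in ("sepsis", "control") or pd.isna(r.index_time):
            continue
        enc = encounters[r.encounter_id]
        d48, di48 = derive_secondary_labels(enc, r.index_time.to_pydatetime()
                                            if hasattr(r.index_time, "to_pydatetime")
                                            else r.index_time)
        rows.append((r.encounter_id, int(r.label == "sepsis"), d48, di48))
    return pd.DataFrame(
        rows, columns=["encounter_id", "label_sepsis", "label_death48", "label_death_or_icu48"]
    )


_OUTCOME_COLS = {
    "sepsis": "label_sepsis",
    "death48": "label_death48",
    "death_icu48": "label_death_or_icu48",
}


def evaluate_grid(
    scores_df: pd.DataFrame,
    eval_samples: pd.DataFrame,
    metrics: tuple[str, ...] = ("AUROC", "AUPRC"),
    outcomes: tuple[str, ...] = ("sepsis",),
    thresholds: dict[str, float] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    scores: tuple[str, ...] | None = None,
    offsets: tuple[int, ...] | None = None,
    modes: tuple[str, ...] | None = None,
    lookbacks: tuple[float, ...] | None = None,
    stratified: bool = False,
) -> pd.DataFrame:
    """Bootstrap estimates for the full factorial of requested combinations.

    ``scores_df``: tidy table (encounter_id, score, offset, mode, lookback,
    total); ``eval_samples``: output of :func:`build_eval_samples`.
    Missing score/offset combinations are reported as warnings in the
    returned frame's ``attrs["missing"]``, not fatal.
    """
    from .scores import VALIDATED_THRESHOLDS

    thresholds = thresholds or VALIDATED_THRESHOLDS
    merged = scores_df.merge(eval_samples, on="encounter_id", how="inner")
    scores = scores or tuple(sorted(merged["score"].unique()))
    offsets = offsets or tuple(sorted(merged["offset"].unique()))
    modes = modes or tuple(sorted(merged["mode"].unique()))
    lookbacks = lookbacks or tuple(sorted(merged["lookback"].unique()))

    rows = []
    missing = []
    combo_idx = 0
    for outcome in outcomes:
        ycol = _OUTCOME_COLS[outcome]
        for sc in scores:
            for lb in lookbacks:
                for mode in modes:
                    for off in offsets:
                        sub = merged[
                            (merged["score"] == sc)
                            & (merged["offset"] == off)
                            & (merged["mode"] == mode)
                            & (merged["lookback"] == lb)
                        ]
                        combo_idx += 1
                        if not len(sub):
                            missing.append((outcome, sc, lb, mode, off))
                            continue
                        y = sub[ycol].to_numpy()
                        s = sub["total"].to_numpy(dtype=float)
                        for metric in metrics:
                            fn = _metric_fn(metric, thresholds.get(sc))
                            try:
                                est = bootstrap(
                                    fn, y, s, n_boot=n_boot,
                                    seed=(seed + 7919 * combo_idx) % (2**31),
                                    stratified=stratified,
                                )
                            except UndefinedMetricError:
                                missing.append((outcome, sc, lb, mode, off, metric))
                                continue
                            rows.append(
                                {
                                    "outcome": outcome, "score": sc, "metric": metric,
                                    "offset": off, "mode": mode, "lookback": lb,
                                    "median": est.median, "ci_low": est.ci_low,
                                    "ci_high": est.ci_high, "point": est.point,
                                    "n": est.n, "n_boot": n_boot,
                                    "n_undefined": est.n_undefined,
                                    "unreliable": est.unreliable,
                                }
                            )
    out = pd.DataFrame(rows)
    out.attrs["missing"] = missing
    return out


def _metric_fn(metric: str, threshold: float | None):
    if metric == "AUROC":
        return auroc
    if metric == "AUPRC":
        return auprc
    if metric in ("recall", "specificity", "precision", "F1"):
        if threshold is None:
            raise ValueError(f"threshold required for metric {metric}")

        def fn(labels, scores, _m=metric, _t=threshold):
            tm = threshold_metrics(labels, scores, _t).as_dict()
            v = tm[_m]
            if np.isnan(v):
                raise UndefinedMetricError(f"{_m} undefined")
            return v

        fn.__name__ = metric
        return fn
    raise ValueError(f"unknown metric {metric!r}")
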