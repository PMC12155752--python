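"""Confusion-matrix metrics, ROC/AUC, bootstrap CIs and the DeLong test.

The positive class is the PD-like class (class A), so sensitivity counts
PD-like detection and specificity counts PPS-like detection.  Metrics with a
zero denominator are reported as ``None`` (undefined), never silently 0.

AUC uses the rank (Mann–Whitney) formulation with midranks for ties, which
equals the trapezoidal area under the empirical ROC curve.  Confidence
intervals are stratified nonparametric bootstrap percentile intervals
(resampling cases within each true class).  Paired AUCs are compared with
DeLong's test from placement-value (structural-component) covariance
estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._seeds import rng_from

__all__ = [
    "ConfusionCounts", "MetricReport", "confusion_from_records",
    "metrics_from_counts", "roc_auc", "bootstrap_ci", "delong_test",
]


@dataclass
class ConfusionCounts:
    """Test-set tallies; positives are the PD-like class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricReport:
    """Point metrics; ``None`` marks a metric undefined on these counts."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    auc: float | None = None
    ci95: dict | None = None

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
            "f1": self.f1,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d


def confusion_from_records(records: pd.DataFrame, positive: str = "A") -> ConfusionCounts:
    """Tally a predictions table (columns true_label, predicted_label)."""
    t = records["true_label"] == positive
    p = records["predicted_label"] == positive
    return ConfusionCounts(
        tp=int((t & p).sum()), fn=int((t & ~p).sum()),
        tn=int((~t & ~p).sum()), fp=int((~t & p).sum()),
    )


def metrics_from_counts(cc: ConfusionCounts) -> MetricReport:
    """Accuracy, sensitivity, specificity, precision and F1 from tallies."""

    def ratio(num, den):
        return num / den if den > 0 else None

    acc = ratio(cc.tp + cc.tn, cc.total)
    sens = ratio(cc.tp, cc.tp + cc.fn)
    spec = ratio(cc.tn, cc.tn + cc.fp)
    prec = ratio(cc.tp, cc.tp + cc.fp)
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2.0 * prec * sens / (prec + sens)
    return MetricReport(acc, sens, spec, prec, f1)


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UO":
        y = (y == "A").astype(int)
    else:
        y = y.astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    return y


def roc_auc(labels, scores) -> float:
    """Mann–Whitney AUC with midranks for ties (positive class = A / 1)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = rankdata(s)
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


_COUNT_METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")


def _metric_from_arrays(name: str, y: np.ndarray, pred: np.ndarray,
                        score: np.ndarray) -> float | None:
    if name == "auc":
        return roc_auc(y, score)
    cc = ConfusionCounts(
        tp=int(((y == 1) & (pred == 1)).sum()), fn=int(((y == 1) & (pred == 0)).sum()),
        tn=int(((y == 0) & (pred == 0)).sum()), fp=int(((y == 0) & (pred == 1)).sum()),
    )
    return getattr(metrics_from_counts(cc), name)


def bootstrap_ci(records: pd.DataFrame, metric_name: str, n_boot: int = 2000,
                 seed: int = 0, alpha: float = 0.05):
    """Stratified bootstrap percentile CI for one metric.

    Cases are resampled with replacement within each true class; resamples
    on which the metric is undefined are skipped (their count is recorded in
    a warning when any occur).
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    if metric_name not in _COUNT_METRICS + ("auc",):
        raise ValueError(f"unknown metric {metric_name!r}")
    y = _check_binary(records["true_label"].to_numpy())
    pred = (records["predicted_label"].to_numpy() == "A").astype(int) \
        if records["predicted_label"].dtype.kind in "UO" \
        else records["predicted_label"].to_numpy().astype(int)
    score = records["score"].to_numpy(dtype=float) if "score" in records else np.zeros_like(y, dtype=float)

    full = _metric_from_arrays(metric_name, y, pred, score)
    if full is None:
        raise ValueError(f"{metric_name} is undefined on the full sample")

    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    rng = rng_from(seed, 101)
    vals = []
    n_skipped = 0
    for _ in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_pos, size=len(idx_pos), replace=True),
            rng.choice(idx_neg, size=len(idx_neg), replace=True),
        ])
        v = _metric_from_arrays(metric_name, y[take], pred[take], score[take])
        if v is None:
            n_skipped += 1
        else:
            vals.append(v)
    if n_skipped:
        warnings.warn(
            f"{n_skipped}/{n_boot} bootstrap resamples had undefined {metric_name}",
            RuntimeWarning, stacklevel=2,
        )
    lo, hi = np.percentile(vals, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def _placements(y: np.ndarray, s: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = len(pos), len(neg)
    # midrank comparison: psi = 1 if pos > neg, 0.5 if tie
    r_all = rankdata(np.concatenate([pos, neg]))
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:n1] - r_pos) / n0
    v01 = 1.0 - (r_all[n1:] - r_neg) / n1
    return v10, v01


def delong_test(labels, scores_model1, scores_model2):
    """Paired DeLong comparison of two AUCs on the same subjects.

    Returns ``(auc1, auc2, z, p)``; ``z = 0, p = 1`` by convention when the
    variance of the difference degenerates (e.g. identical score vectors).
    """
    y = _check_binary(labels)
    s1 = np.asarray(scores_model1, dtype=float)
    s2 = np.asarray(scores_model2, dtype=float)
    if len(s1) != len(y) or len(s2) != len(y):
        raise ValueError("scores must be paired with labels")
    v10_1, v01_1 = _placements(y, s1)
    v10_2, v01_2 = _placements(y, s2)
    # the mean placement equals the rank AUC; use the rank form directly so
    # the reported AUCs are bit-identical to roc_auc()
    auc1, auc2 = roc_auc(y, s1), roc_auc(y, s2)
    n1, n0 = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]))
    s01 = np.cov(np.stack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1 \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0 or not np.isfinite(var):
        return auc1, auc2, 0.0, 1.0
    z = (auc1 - auc2) / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return auc1, auc2, float(z), p
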