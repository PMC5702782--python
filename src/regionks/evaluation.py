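"""Evaluation harness: the "Max" baseline, ROC/AUC, and the standard
threshold metrics.

The baseline against which the region-level tests are judged is the common
practice of classifying a region as a target iff its single best window
score exceeds a threshold chosen so that ~98% of the known training sites
would be recovered.  ROC curves are swept over the ranking statistic of
each method (D for KS, the standardized AD statistic for AD and the
hybrid, the best window score for Max), with the positives and the
ORF-interior putative negatives as the two labeled sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .enrichment import ks_d_statistic, ks_pvalue
from .pswm import ScoreSample

__all__ = [
    "ThresholdMetrics",
    "EvalReport",
    "max_score",
    "standard_threshold",
    "roc",
    "evaluate_at_threshold",
    "confusion_from_hits",
    "compare_d_enrichment",
]


@dataclass
class ThresholdMetrics:
    """Confusion counts and derived metrics at one threshold.

    sensitivity = TP / (TP + FN), specificity = TN / (TN + FP),
    accuracy = (TP + TN) / (TP + FP + FN + TN).
    """

    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / (self.tp + self.fp + self.tn + self.fn)


@dataclass
class EvalReport:
    """ROC curve plus optional threshold metrics for one method."""

    method: str
    roc_points: np.ndarray  # (k, 2) columns FPR, TPR, sorted by threshold
    auc: float
    at_threshold: Optional[ThresholdMetrics] = None


def max_score(sample: ScoreSample) -> float:
    """The region's best window score (the "Max" baseline statistic)."""
    if sample.n == 0:
        raise ValueError(f"region {sample.region_id!r}: empty score sample")
    return float(sample.scores.max())


def standard_threshold(
    training_site_scores: Sequence[float], recovery: float = 0.98
) -> float:
    """The standard Max-method threshold: the largest score value t such
    that at least ``recovery`` of the known training sites score >= t.

    With N training scores this is the ceil(recovery * N)-th largest score
    (ties broken downward, so ties at t are all recovered)."""
    scores = np.sort(np.asarray(training_site_scores, dtype=float))
    n = scores.size
    if n == 0:
        raise ValueError("no training site scores")
    if not 0.0 < recovery <= 1.0:
        raise ValueError("recovery must be in (0, 1]")
    if n < 10:
        import warnings

        warnings.warn(
            f"only {n} training scores; the recovery threshold is unstable",
            stacklevel=2,
        )
    r = math.ceil(recovery * n)
    return float(scores[n - r])


def roc(
    pos_stats: Sequence[float],
    neg_stats: Sequence[float],
    larger_is_hit: bool = True,
    method: str = "",
) -> EvalReport:
    """ROC curve over all distinct statistic values (ties collapse into a
    single threshold step) and trapezoidal AUC."""
    pos = np.asarray(pos_stats, dtype=float)
    neg = np.asarray(neg_stats, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both positive and negative statistics are required")
    for name, arr in (("positive", pos), ("negative", neg)):
        bad = np.flatnonzero(np.isnan(arr))
        if bad.size:
            raise ValueError(f"NaN statistic for {name} item {bad[0]}")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    if not larger_is_hit:
        s = -s
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    return EvalReport(
        method=method,
        roc_points=np.column_stack([fpr, tpr]),
        auc=float(_sk_auc(fpr, tpr)),
    )


def evaluate_at_threshold(
    pos_stats: Sequence[float],
    neg_stats: Sequence[float],
    threshold: float,
    larger_is_hit: bool = True,
) -> ThresholdMetrics:
    """Confusion counts at a fixed threshold.

    With ``larger_is_hit`` a region is a hit iff its statistic is >= the
    threshold (the Max-method convention, so sites scoring exactly at the
    recovery threshold are recovered); otherwise iff it is strictly below
    (the P-value convention, hit iff p < alpha)."""
    pos = np.asarray(pos_stats, dtype=float)
    neg = np.asarray(neg_stats, dtype=float)
    if larger_is_hit:
        pos_hits, neg_hits = pos >= threshold, neg >= threshold
    else:
        pos_hits, neg_hits = pos < threshold, neg < threshold
    return confusion_from_hits(pos_hits, neg_hits, threshold=threshold)


def confusion_from_hits(
    pos_hits: Sequence[bool],
    neg_hits: Sequence[bool],
    threshold: float = float("nan"),
) -> ThresholdMetrics:
    pos_hits = np.asarray(pos_hits, dtype=bool)
    neg_hits = np.asarray(neg_hits, dtype=bool)
    if pos_hits.size == 0 or neg_hits.size == 0:
        raise ValueError("no positives (or no negatives) to evaluate")
    return ThresholdMetrics(
        threshold=threshold,
        tp=int(pos_hits.sum()),
        fn=int((~pos_hits).sum()),
        fp=int(neg_hits.sum()),
        tn=int((~neg_hits).sum()),
    )


def compare_d_enrichment(
    pos_D: Sequence[float], neg_D: Sequence[float]
) -> float:
    """One-sided two-sample KS P-value that the positive set's D scores are
    stochastically larger than the negative set's (used to compare the two
    background choices)."""
    pos = np.asarray(pos_D, dtype=float)
    neg = np.asarray(neg_D, dtype=float)
    if pos.size < 5 or neg.size < 5:
        raise ValueError("need at least 5 D scores in each set")
    d = ks_d_statistic(pos, np.sort(neg))
    return ks_pvalue(d, pos.size, neg.size)
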