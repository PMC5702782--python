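"""End-to-end orchestration: scan region sets, run every test, build ROC
reports.  This is what the CLI and the benchmark scripts call."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .backgrounds import BackgroundDistribution
from .enrichment import ad_test, hybrid_ks_ad, ks_one_sided
from .evaluation import (
    EvalReport,
    confusion_from_hits,
    evaluate_at_threshold,
    max_score,
    roc,
    standard_threshold,
)
from .pswm import ScoreSample, Scorer, scan_region
from .regions import GenomicRegion

__all__ = ["score_region_set", "method_table", "evaluate_methods"]

#: ranking statistic assigned to hybrid-filtered regions so they sort below
#: every region that reached the AD stage
_FILTERED_RANK = -1e12


def score_region_set(
    regions: Sequence[GenomicRegion],
    scorer: Scorer,
    strands: str = "both",
) -> list[ScoreSample]:
    return [scan_region(scorer, r, strands=strands) for r in regions]


def method_table(
    samples: Sequence[ScoreSample],
    background: BackgroundDistribution,
    alpha: float = 0.05,
    ks_filter_p: float = 0.5,
) -> pd.DataFrame:
    """Per-region statistics for all four methods.

    Columns: the KS D score and P-value, the standardized AD statistic and
    P-value, the hybrid ranking statistic and classification, and the best
    window score (Max baseline).
    """
    rows = []
    for s in samples:
        ks = ks_one_sided(s, background, alpha=alpha)
        ad = ad_test(s, background, alpha=alpha)
        hy = hybrid_ks_ad(s, background, ks_filter_p=ks_filter_p, alpha=alpha)
        rows.append(
            {
                "region_id": s.region_id,
                "n": s.n,
                "D": ks.D,
                "p_ks": ks.p_value,
                "hit_ks": ks.classified_target,
                "A2": ad.A2,
                "p_ad": ad.p_value,
                "hit_ad": ad.classified_target,
                "hybrid_stat": hy.A2 if hy.A2 is not None else _FILTERED_RANK,
                "hybrid_filtered": hy.A2 is None,
                "hit_hybrid": hy.classified_target,
                "max_score": max_score(s),
            }
        )
    return pd.DataFrame(rows)


def evaluate_methods(
    pos_samples: Sequence[ScoreSample],
    neg_samples: Sequence[ScoreSample],
    background: BackgroundDistribution,
    site_scores: Optional[Sequence[float]] = None,
    alpha: float = 0.05,
    recovery: float = 0.98,
    ks_filter_p: float = 0.5,
) -> tuple[dict[str, EvalReport], pd.DataFrame]:
    """ROC + standard-threshold metrics for KS, AD, the hybrid, and Max.

    ``site_scores`` (known training-site scores) set the Max recovery
    threshold; without them the Max report carries no threshold metrics.
    Returns the per-method reports and the combined per-region table (with
    a ``label`` column, 1 for positives).
    """
    if not pos_samples:
        raise ValueError("no positives: cannot evaluate")
    if not neg_samples:
        raise ValueError("no negatives: cannot evaluate")
    pos = method_table(pos_samples, background, alpha, ks_filter_p)
    neg = method_table(neg_samples, background, alpha, ks_filter_p)
    pos["label"], neg["label"] = 1, 0

    reports: dict[str, EvalReport] = {}

    rep = roc(pos["D"], neg["D"], larger_is_hit=True, method="KS")
    rep.at_threshold = evaluate_at_threshold(
        pos["p_ks"], neg["p_ks"], alpha, larger_is_hit=False
    )
    reports["KS"] = rep

    rep = roc(pos["A2"], neg["A2"], larger_is_hit=True, method="AD")
    rep.at_threshold = evaluate_at_threshold(
        pos["p_ad"], neg["p_ad"], alpha, larger_is_hit=False
    )
    reports["AD"] = rep

    rep = roc(
        pos["hybrid_stat"], neg["hybrid_stat"], larger_is_hit=True, method="HYBRID"
    )
    rep.at_threshold = confusion_from_hits(
        pos["hit_hybrid"], neg["hit_hybrid"], threshold=alpha
    )
    reports["HYBRID"] = rep

    rep = roc(pos["max_score"], neg["max_score"], larger_is_hit=True, method="MAX")
    if site_scores is not None and len(site_scores):
        t = standard_threshold(site_scores, recovery=recovery)
        rep.at_threshold = evaluate_at_threshold(
            pos["max_score"], neg["max_score"], t, larger_is_hit=True
        )
    reports["MAX"] = rep

    return reports, pd.concat([pos, neg], ignore_index=True)
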