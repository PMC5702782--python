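"""Region-level enrichment tests.

This is the statistical core of the package: instead of thresholding the
single best motif hit, an entire region's window-score distribution is
compared with an empirical background distribution.

The primary test is a one-sided two-sample Kolmogorov-Smirnov statistic on
survival functions,

    D = sup_x [ S_region(x) - S_background(x) ],      S(x) = P(score >= x),

floored at 0, so only *overrepresentation of high scores* can produce a
hit; a region depleted of strong windows has D ~ 0 no matter how different
its distribution is.  The asymptotic one-sided two-sample P-value

    p = exp(-2 D^2 n m / (n + m))

is used (capped at 1), and a permutation oracle is provided to validate it.

The Anderson-Darling alternative uses the two-sample rank statistic with
midrank tie correction (Scholz-Stephens), standardized by its exact null
mean and variance; a hybrid first discards regions whose KS P-value is
clearly non-significant (>= 0.5 by default) and ranks the remainder by the
AD statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .backgrounds import BackgroundDistribution
from .pswm import ScoreSample

__all__ = [
    "EnrichmentResult",
    "ks_one_sided",
    "ad_test",
    "hybrid_ks_ad",
    "permutation_pvalue",
    "ks_d_statistic",
    "ks_pvalue",
    "ad_statistic",
    "results_table",
    "write_results_tsv",
]


# ---------------------------------------------------------------------------
# Result container


@dataclass
class EnrichmentResult:
    """Per-region test outcome."""

    region_id: str
    test: str  # KS | AD | HYBRID | MAX
    p_value: float
    n: int
    m: int
    D: Optional[float] = None
    A2: Optional[float] = None  # standardized AD statistic ('adstat')
    classified_target: bool = False
    unreliable: bool = False


# ---------------------------------------------------------------------------
# One-sided KS


def ks_d_statistic(sample: np.ndarray, background_sorted: np.ndarray) -> float:
    """Exact sup over all pooled observed values of
    S_sample(x) - S_background(x), floored at 0."""
    sample_sorted = np.sort(np.asarray(sample, dtype=float))
    n = sample_sorted.size
    m = background_sorted.size
    pooled = np.unique(np.concatenate([sample_sorted, background_sorted]))
    s_s = (n - np.searchsorted(sample_sorted, pooled, side="left")) / n
    s_b = (m - np.searchsorted(background_sorted, pooled, side="left")) / m
    return max(0.0, float(np.max(s_s - s_b)))


def ks_pvalue(d: float, n: int, m: int) -> float:
    """Asymptotic one-sided two-sample P-value, capped at 1."""
    return min(1.0, math.exp(-2.0 * d * d * n * m / (n + m)))


def _as_arrays(
    sample: Union[ScoreSample, np.ndarray],
    background: Union[BackgroundDistribution, np.ndarray],
) -> tuple[str, np.ndarray, np.ndarray]:
    if isinstance(sample, ScoreSample):
        region_id, s = sample.region_id, sample.scores
        sid = sample.scanner_id
    else:
        region_id, s, sid = "", np.asarray(sample, dtype=float), ""
    if isinstance(background, BackgroundDistribution):
        b = background.scores
        if sid and background.scanner_id and sid != background.scanner_id:
            warnings.warn(
                f"sample scanner {sid!r} != background scanner "
                f"{background.scanner_id!r}; the comparison is not meaningful",
                stacklevel=3,
            )
    else:
        b = np.sort(np.asarray(background, dtype=float))
    if s.size == 0 or b.size == 0:
        raise ValueError("empty sample or background")
    return region_id, s, b


def ks_one_sided(
    sample: Union[ScoreSample, np.ndarray],
    background: Union[BackgroundDistribution, np.ndarray],
    alpha: float = 0.05,
    n_min: int = 10,
) -> EnrichmentResult:
    """One-sided KS enrichment test of a region against the background."""
    region_id, s, b = _as_arrays(sample, background)
    d = ks_d_statistic(s, b)
    p = ks_pvalue(d, s.size, b.size)
    return EnrichmentResult(
        region_id=region_id,
        test="KS",
        D=d,
        p_value=p,
        n=s.size,
        m=b.size,
        classified_target=p < alpha,
        unreliable=(s.size < n_min or b.size < s.size),
    )


# ---------------------------------------------------------------------------
# Two-sample Anderson-Darling (Scholz-Stephens, midrank tie correction)

_AD_B0 = np.array([0.675, 1.281, 1.645, 1.960, 2.326, 2.573, 3.085])
_AD_B1 = np.array([-0.245, 0.250, 0.678, 1.149, 1.822, 2.364, 3.615])
_AD_B2 = np.array([-0.105, -0.305, -0.481, -0.511, -0.669, -0.569, -0.497])
_AD_SIG = np.array([0.25, 0.10, 0.05, 0.025, 0.01, 0.005, 0.001])


def ad_statistic(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample AD statistic with midrank ties.

    Returns ``(A2akN, Tk)`` where ``A2akN`` is the rank-based statistic and
    ``Tk`` its standardization by the exact null mean (k-1) and standard
    deviation."""
    samples = [np.asarray(x, dtype=float), np.asarray(y, dtype=float)]
    k = 2
    N = sum(s.size for s in samples)
    pooled = np.sort(np.concatenate(samples))
    z, l = np.unique(pooled, return_counts=True)
    if z.size < 2:
        raise ValueError("pooled sample is constant; AD statistic undefined")
    b_j = np.cumsum(l) - l / 2.0  # midrank cumulative count
    denom = b_j * (N - b_j) - N * l / 4.0
    a2 = 0.0
    for s in samples:
        ss = np.sort(s)
        below = np.searchsorted(ss, z, side="left")
        equal = np.searchsorted(ss, z, side="right") - below
        m_ij = below + equal / 2.0
        num = (N * m_ij - s.size * b_j) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = np.where(denom > 0, l / N * num / denom, 0.0)
        a2 += terms.sum() / s.size
    a2 *= (N - 1) / N

    # exact null variance (Scholz & Stephens)
    n_i = np.array([s.size for s in samples], dtype=float)
    H = (1.0 / n_i).sum()
    i = np.arange(1, N)
    h_cum = np.cumsum(1.0 / i)  # h_cum[j-1] = sum_{t=1..j} 1/t
    h = h_cum[-1]
    # g = sum_{i=1}^{N-2} (1/(N-i)) * (h_{N-1} - h_i)
    ii = np.arange(1, N - 1)
    g = float(np.sum((h - h_cum[ii - 1]) / (N - ii)))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    tk = (a2 - (k - 1)) / math.sqrt(max(var, 1e-300))
    return float(a2), float(tk)


def _ad_pvalue(tk: float, k: int = 2) -> float:
    """Standardized-statistic P-value via the Scholz-Stephens critical-value
    interpolation (quadratic fit of log significance vs critical value,
    extrapolated beyond the tabulated [0.001, 0.25] range and capped at 1)."""
    m = k - 1
    tm = _AD_B0 + _AD_B1 / math.sqrt(m) + _AD_B2 / m
    pf = np.polyfit(tm, np.log(_AD_SIG), 2)
    tmin = float(tm.min())
    if tk < tmin:
        # linear continuation below the tabulated range (the quadratic
        # turns upward there), so clearly-null statistics get p -> 1
        slope = float(np.polyval(np.polyder(pf), tmin))
        logp = float(np.polyval(pf, tmin)) + slope * (tk - tmin)
    else:
        logp = float(np.polyval(pf, tk))
    return math.exp(min(logp, 0.0))


def ad_test(
    sample: Union[ScoreSample, np.ndarray],
    background: Union[BackgroundDistribution, np.ndarray],
    alpha: float = 0.05,
    n_min: int = 10,
    mode: str = "two-sample",
) -> EnrichmentResult:
    """Anderson-Darling enrichment test of a region against the background.

    ``mode="two-sample"`` (default) treats the background as the second
    sample; ``mode="one-sample"`` treats the background's empirical CDF as a
    fixed reference distribution (statistic only; no calibrated P-value is
    attached because the reference is itself estimated)."""
    region_id, s, b = _as_arrays(sample, background)
    if mode == "two-sample":
        a2, tk = ad_statistic(s, b)
        p = _ad_pvalue(tk)
    elif mode == "one-sample":
        a2 = _one_sample_a2(s, b)
        tk = a2
        p = float("nan")
    else:
        raise ValueError("mode must be 'two-sample' or 'one-sample'")
    return EnrichmentResult(
        region_id=region_id,
        test="AD",
        A2=tk,
        p_value=p,
        n=s.size,
        m=b.size,
        classified_target=bool(p < alpha),
        unreliable=(s.size < n_min or b.size < s.size),
    )


def _one_sample_a2(sample: np.ndarray, background_sorted: np.ndarray) -> float:
    """One-sample A2 of the sample against the background empirical CDF
    (smoothed to avoid 0/1 probabilities)."""
    x = np.sort(sample)
    n = x.size
    m = background_sorted.size
    f = (np.searchsorted(background_sorted, x, side="right") + 0.5) / (m + 1.0)
    i = np.arange(1, n + 1)
    return float(
        -n - np.sum((2 * i - 1) * (np.log(f) + np.log(1.0 - f[::-1]))) / n
    )


# ---------------------------------------------------------------------------
# KS -> AD hybrid


def hybrid_ks_ad(
    sample: Union[ScoreSample, np.ndarray],
    background: Union[BackgroundDistribution, np.ndarray],
    ks_filter_p: float = 0.5,
    alpha: float = 0.05,
    n_min: int = 10,
) -> EnrichmentResult:
    """KS-filtered AD test.

    Regions whose KS P-value is >= ``ks_filter_p`` (a deliberately liberal
    threshold: only clearly non-significant regions are removed) are
    classified non-targets without computing AD; the rest are tested and
    ranked by AD."""
    ks = ks_one_sided(sample, background, alpha=alpha, n_min=n_min)
    if ks.p_value >= ks_filter_p:
        return EnrichmentResult(
            region_id=ks.region_id,
            test="HYBRID",
            D=ks.D,
            A2=None,
            p_value=ks.p_value,
            n=ks.n,
            m=ks.m,
            classified_target=False,
            unreliable=ks.unreliable,
        )
    ad = ad_test(sample, background, alpha=alpha, n_min=n_min)
    return EnrichmentResult(
        region_id=ad.region_id,
        test="HYBRID",
        D=ks.D,
        A2=ad.A2,
        p_value=ad.p_value,
        n=ad.n,
        m=ad.m,
        classified_target=ad.classified_target,
        unreliable=ad.unreliable,
    )


# ---------------------------------------------------------------------------
# Permutation oracle


def permutation_pvalue(
    sample: Union[ScoreSample, np.ndarray],
    background: Union[BackgroundDistribution, np.ndarray],
    n_perm: int = 10000,
    rng_seed: Union[int, np.random.Generator, None] = 0,
    statistic: str = "KS",
) -> float:
    """Permutation P-value for the KS (D) or AD (A2) statistic: pool both
    samples, re-split at the original sizes ``n_perm`` times, and return
    ``(1 + #{perm stat >= observed}) / (n_perm + 1)``."""
    if n_perm < 1000:
        warnings.warn(
            f"n_perm={n_perm} is small; permutation P-values will be coarse",
            stacklevel=2,
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    _, s, b = _as_arrays(sample, background)
    n = s.size
    pooled = np.concatenate([s, b])
    if statistic == "KS":
        stat = lambda x, y: ks_d_statistic(x, np.sort(y))
    elif statistic == "AD":
        stat = lambda x, y: ad_statistic(x, y)[0]
    else:
        raise ValueError("statistic must be 'KS' or 'AD'")
    observed = stat(s, b)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm[:n], perm[n:]) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Result tables


def results_table(
    results: Sequence[EnrichmentResult], adjust: bool = True
) -> pd.DataFrame:
    """Tabulate per-region results; optionally add a Benjamini-Hochberg
    adjusted P-value column (the default classification nevertheless uses
    raw P-values at alpha)."""
    df = pd.DataFrame(
        {
            "region_id": [r.region_id for r in results],
            "test": [r.test for r in results],
            "n": [r.n for r in results],
            "m": [r.m for r in results],
            "D": [r.D if r.D is not None else np.nan for r in results],
            "A2": [r.A2 if r.A2 is not None else np.nan for r in results],
            "p_value": [r.p_value for r in results],
            "classified_target": [r.classified_target for r in results],
            "unreliable": [r.unreliable for r in results],
        }
    )
    if adjust and len(df):
        from scipy.stats import false_discovery_control

        p = df["p_value"].to_numpy(dtype=float)
        ok = np.isfinite(p)
        adj = np.full_like(p, np.nan)
        if ok.any():
            adj[ok] = false_discovery_control(p[ok], method="bh")
        df.insert(7, "p_adjusted", adj)
    return df


def write_results_tsv(results: Sequence[EnrichmentResult], path) -> None:
    results_table(results).to_csv(path, sep="\t", index=False)
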