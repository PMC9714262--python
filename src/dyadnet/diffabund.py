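"""Per-taxon two-group comparisons: Wilcoxon rank-sum with a
Hodges-Lehmann shift estimate and CI, plus Benjamini-Hochberg FDR.

The exact rank-sum null distribution is used for combined n <= 20 with no
ties; otherwise a tie-corrected, continuity-corrected normal approximation.
Significance across taxa is flagged at q < 0.25, and the FDR family is one
(sample type x contrast) run, never pooled across sample types.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import DataError, TaxaTable, to_relative

EXACT_MAX_N = 20
Q_THRESHOLD = 0.25


@dataclass
class TaxonTestResult:
    taxon: str
    n_x: int
    n_y: int
    statistic: float  # Mann-Whitney U for the first group
    p: float
    hl_estimate: float
    ci_lower: float
    ci_upper: float
    q: float = np.nan
    significant: bool = False


@lru_cache(maxsize=None)
def _u_counts(n: int, m: int) -> tuple[int, ...]:
    """c[u] = #subsets of size n of ranks 1..n+m whose U statistic equals u.

    Recurrence on whether the largest remaining rank is in the x-sample
    (contributing m to U) or the y-sample.
    """
    if n == 0 or m == 0:
        return (1,)
    with_x = _u_counts(n - 1, m)
    without = _u_counts(n, m - 1)
    res = [0] * (n * m + 1)
    for u, c in enumerate(with_x):
        res[u + m] += c
    for u, c in enumerate(without):
        res[u] += c
    return tuple(res)


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = _u_counts(n, m)
    total = sum(counts)
    mean = n * m / 2.0
    dev = abs(u - mean)
    tail = sum(c for uu, c in enumerate(counts) if abs(uu - mean) >= dev - 1e-9)
    return min(1.0, tail / total)


def _exact_critical_u(n: int, m: int, alpha: float) -> int:
    """Largest k with P(U <= k) <= alpha/2 under the exact null; -1 if none."""
    counts = _u_counts(n, m)
    total = sum(counts)
    cum = 0
    k = -1
    for u, c in enumerate(counts):
        cum += c
        if cum / total <= alpha / 2.0:
            k = u
        else:
            break
    return k


def wilcoxon_hl(
    x, y, conf_level: float = 0.95, continuity: bool = True
) -> TaxonTestResult:
    """Rank-sum test of two samples with Hodges-Lehmann shift estimate.

    The HL estimate is the median of all pairwise differences x_i - y_j;
    its CI comes from inverting the rank-sum test (order statistics of the
    pairwise differences at the critical rank).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("wilcoxon_hl needs at least 2 observations per group")
    n, m = x.size, y.size
    nm = n * m
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))

    ties = len(np.unique(np.concatenate([x, y]))) < n + m
    u1 = float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").statistic)
    if n + m <= EXACT_MAX_N and not ties:
        p = _exact_two_sided_p(u1, n, m)
        k = _exact_critical_u(n, m, 1.0 - conf_level)
    else:
        p = float(stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=continuity).pvalue)
        z = stats.norm.ppf(1.0 - (1.0 - conf_level) / 2.0)
        k = int(np.floor(nm / 2.0 - z * np.sqrt(nm * (n + m + 1) / 12.0)))
    if k < 0:
        ci_lo, ci_hi = float(diffs[0]), float(diffs[-1])
    else:
        ci_lo = float(diffs[min(k + 1, nm - 1)])
        ci_hi = float(diffs[max(nm - k - 2, 0)])
    ci_lo = min(ci_lo, hl)
    ci_hi = max(ci_hi, hl)
    return TaxonTestResult(
        taxon="", n_x=n, n_y=m, statistic=u1, p=p,
        hl_estimate=hl, ci_lower=ci_lo, ci_upper=ci_hi,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise DataError("bh_fdr expects a 1-d list of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def differential_abundance(
    table: TaxaTable,
    labels,
    conf_level: float = 0.95,
    continuity: bool = True,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Wilcoxon + HL per taxon between two groups, BH-corrected across taxa.

    ``labels``: boolean/two-level vector aligned with the table's samples;
    True (or the first level encountered) defines group x.
    """
    labels = np.asarray(labels)
    if labels.size != table.n_samples:
        raise DataError("labels length does not match sample count")
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise DataError(f"need exactly 2 groups, got {len(levels)}")
    mask = labels == levels[0]
    rel = table if table.scale == "relative" else to_relative(table)
    results: list[TaxonTestResult] = []
    for taxon, row in zip(rel.taxa_ids, rel.counts):
        r = wilcoxon_hl(row[mask], row[~mask], conf_level=conf_level,
                        continuity=continuity)
        r.taxon = taxon
        results.append(r)
    q = bh_fdr([r.p for r in results])
    for r, qv in zip(results, q):
        r.q = float(qv)
        r.significant = bool(qv < q_threshold)
    return pd.DataFrame(
        [{"taxon": r.taxon, "n_x": r.n_x, "n_y": r.n_y, "statistic": r.statistic,
          "p": r.p, "hl_estimate": r.hl_estimate, "ci_lower": r.ci_lower,
          "ci_upper": r.ci_upper, "q": r.q, "significant": r.significant}
         for r in results]
    )
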