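"""Rank-based two-sample tests shared by the enrichment and expression stages.

The Wilcoxon rank-sum / Mann-Whitney U test is used for SE-vs-TE density
contrasts and for knockdown log2 fold-change group contrasts. Small samples
without ties use the exact null distribution; everything else uses the normal
approximation with tie-corrected variance (no continuity correction, so that
a perfectly balanced U gives p = 1).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import stats as sps

EXACT_MAX_COMBINED_N = 50


def mann_whitney_u(a, b) -> float:
    """U statistic for sample ``a`` vs ``b`` (number of (a, b) pairs a > b,
    counting ties as half)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: len(a)].sum()
    return float(r_a - len(a) * (len(a) + 1) / 2.0)


def rank_sum_test(a, b) -> float:
    """Two-sided rank-sum p-value.

    Exact null distribution when the combined sample is small (<= 50) and
    tie-free; otherwise normal approximation with tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(pooled) <= EXACT_MAX_COMBINED_N:
        return float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    return _asymptotic_p(a, b)


def _asymptotic_p(a, b) -> float:
    n1, n2 = len(a), len(b)
    n = n1 + n2
    u = mann_whitney_u(a, b)
    mean = n1 * n2 / 2.0
    pooled = np.concatenate([a, b])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0  # all observations identical
    z = (u - mean) / math.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def exact_enumeration_p(a, b) -> float:
    """Brute-force two-sided permutation p over all group assignments.

    Independent reference implementation for tiny samples; enumerates every
    C(n1+n2, n1) split of the pooled values and counts splits whose U is at
    least as extreme (two-sided, measured as |U - n1*n2/2|).
    """
    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    center = n1 * len(b) / 2.0
    obs = abs(mann_whitney_u(a, b) - center)
    hits = total = 0
    idx = range(len(pooled))
    for comb in itertools.combinations(idx, n1):
        comb_set = set(comb)
        aa = [pooled[i] for i in comb]
        bb = [pooled[i] for i in idx if i not in comb_set]
        total += 1
        if abs(mann_whitney_u(aa, bb) - center) >= obs - 1e-12:
            hits += 1
    return hits / total
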