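"""Statistical tests used across the pipeline.

Thin, validated wrappers: Fisher's exact test (two-sided by the
probability-mass rule) and the Wilcoxon rank-sum test (exact null for small
tie-free samples, normal approximation with tie and continuity corrections
otherwise).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    Returns (sample odds ratio, p-value).  The two-sided p sums the
    probabilities of all tables with probability <= that of the observed
    table, at fixed margins.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("table cells must be nonnegative")
    if not np.all(arr == np.floor(arr)):
        raise ValueError("table cells must be integers")
    res = sps.fisher_exact(arr.astype(int), alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_rank_sum(
    sample_a, sample_b, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Wilcoxon rank-sum test; returns (rank-sum W of sample_a, p-value).

    The exact null distribution is used when min(n, m) <= 10 and there are
    no ties; otherwise the normal approximation with midrank tie correction
    and continuity correction.  ``alternative`` refers to sample_a relative
    to sample_b ('less' = a tends smaller).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(a.size, b.size) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative=alternative, method=method, use_continuity=True
    )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return w, float(res.pvalue)
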