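"""Shared statistical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["rank_sum_p"]


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p-value with a degenerate-data guard.

    If the pooled sample has no variation at all (every value identical) the
    test is uninformative and p = 1 is returned rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    # exact null distribution when feasible and tie-free; ties force the
    # tie-corrected normal approximation (scipy supports ties only there)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not has_ties and max(a.size, b.size) <= 30) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
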