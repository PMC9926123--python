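"""Nonparametric statistics used across the pipeline.

``rank_sum_W`` reports the Wilcoxon rank-sum statistic in the R
convention: W = (sum of pooled mid-ranks of the first sample) -
n_x (n_x + 1) / 2, i.e. the Mann-Whitney U of the first sample, ranging
over [0, n_x n_y].  The two-sided p-value uses the exact distribution for
small tie-free samples and the tie-corrected normal approximation
otherwise (scipy's method='auto').
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps


def rank_sum_W(x, y) -> tuple[float, float]:
    """R-convention Wilcoxon rank-sum W of ``x`` vs ``y`` and two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples need at least one observation")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    w = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
    p = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto").pvalue
    return float(w), float(p)


def one_sample_t(x, popmean: float) -> tuple[float, float]:
    """One-sample t-test of ``x`` against a theoretical value."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0 if x[0] == popmean else float("inf"), 1.0 if x[0] == popmean else 0.0
    res = sps.ttest_1samp(x, popmean)
    return float(res.statistic), float(res.pvalue)


def sign_test(x, theoretical: float) -> tuple[int, float]:
    """Sign test of a sample against a theoretical value.

    Returns the number of observations above the value among non-ties and
    the two-sided binomial p-value.
    """
    x = np.asarray(x, dtype=float)
    above = int((x > theoretical).sum())
    below = int((x < theoretical).sum())
    n = above + below
    if n == 0:
        return 0, 1.0
    p = sps.binomtest(above, n, 0.5, alternative="two-sided").pvalue
    return above, float(p)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (mid-ranks, Pearson on ranks)."""
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
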