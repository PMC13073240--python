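"""Shared statistical utilities: BH adjustment, rank-sum tests, t-tests.

These are thin, explicitly-documented wrappers over scipy/statsmodels so
every module applies the same conventions (two-sided tests, natural-log
fold changes, step-up FDR across the stated batch).
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=np.float64)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x: np.ndarray, y: np.ndarray, axis: int = 0) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) p-values.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise (scipy's ``auto`` policy).
    Supports vectorized input along ``axis`` for per-gene testing.
    """
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", axis=axis, method="auto")
    return np.atleast_1d(res.pvalue)


def student_t_test(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sided two-sample Student's t-test (equal variance pooled).

    Degenerate inputs (zero variance in both groups with equal means)
    return ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n ≥ 2")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return (np.inf if np.mean(a) > np.mean(b) else -np.inf), 0.0
    t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def ovr_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """One-vs-rest ROC AUC from one class's score column (ties count 1/2).

    Equivalent to the Mann–Whitney statistic U / (n_pos × n_neg).
    """
    scores = np.asarray(scores, dtype=np.float64)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = scipy.stats.rankdata(scores)
    u = ranks[positives].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
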