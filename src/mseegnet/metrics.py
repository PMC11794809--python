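"""Classification metrics and the paired significance test.

Accuracy is the multiclass generalization of (TP+TN)/(TP+TN+FP+FN): the
confusion-matrix trace over its total, in percent.  Cohen's kappa is
(P_o - P_e)/(1 - P_e) with P_o the observed agreement and P_e the chance
agreement from the row/column marginals.  The Wilcoxon signed-rank test is
computed against its exact null distribution (all 2^n equally likely sign
assignments of the ranked absolute differences), which is what small
subject counts (n = 9 or 14) call for; zero differences are dropped and
tied absolute differences receive average ranks.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "confusion_matrix",
    "accuracy",
    "kappa",
    "wilcoxon_signed_rank",
]


def confusion_matrix(y_true, y_pred, n_classes: int | None = None) -> np.ndarray:
    """Counts matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(confusion: np.ndarray) -> float:
    """Percent correct: 100 * trace / total."""
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    return float(100.0 * np.trace(cm) / total)


def kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa, (P_o - P_e) / (1 - P_e)."""
    cm = np.asarray(confusion, dtype=np.float64)
    total = cm.sum()
    if cm.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if p_e >= 1.0:
        raise ValueError("chance agreement P_e = 1; kappa undefined "
                         "(all mass in a single row/column pair)")
    return float((p_o - p_e) / (1.0 - p_e))


def _exact_signed_rank_cdf(ranks2: np.ndarray) -> np.ndarray:
    """PMF of W+ over doubled ranks, by generating-function convolution.

    Equivalent to enumerating all 2^n sign assignments: the polynomial
    prod_i (1 + x^(2 r_i)) counts assignments by doubled rank sum.  Doubling
    makes average (half-integer) tie ranks exact integers.
    """
    max_sum = int(ranks2.sum())
    pmf = np.zeros(max_sum + 1, dtype=np.float64)
    pmf[0] = 1.0
    top = 0
    for r in ranks2:
        r = int(r)
        nxt = pmf.copy()
        nxt[r:top + r + 1] += pmf[:top + 1]
        pmf = nxt
        top += r
    return pmf / pmf.sum()


def wilcoxon_signed_rank(a, b, zero_policy: str = "drop",
                         alternative: str = "two-sided") -> float:
    """Exact Wilcoxon signed-rank p-value for paired scores.

    Zero differences are dropped (Wilcoxon's original prescription); tied
    absolute differences get average ranks.  Exact for any n this package
    meets in practice (the convolution is polynomial, not a 2^n loop, but
    yields the same null distribution).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D and equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if zero_policy == "drop":
        d = d[d != 0.0]
    elif zero_policy != "keep":
        raise ValueError("zero_policy must be 'drop' or 'keep'")
    if d.size == 0:
        raise ValueError("all differences are zero")
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(d.size, dtype=np.float64)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < d.size:
        j = i
        while j + 1 < d.size and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        avg = (pos + pos + (j - i)) / 2.0
        ranks[order[i:j + 1]] = avg
        pos += j - i + 1
        i = j + 1
    ranks2 = np.round(2.0 * ranks).astype(np.int64)
    w_plus2 = int(np.round(2.0 * ranks[d > 0].sum()))
    pmf = _exact_signed_rank_cdf(ranks2)
    cdf = np.cumsum(pmf)
    p_le = float(cdf[w_plus2])
    p_ge = float(pmf[w_plus2:].sum())
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(p_le, p_ge))
    if alternative == "greater":    # a tends to exceed b
        return p_ge
    if alternative == "less":
        return p_le
    raise ValueError("alternative must be two-sided, greater or less")
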