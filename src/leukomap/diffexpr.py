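"""Differential expression between two cell groups.

The recipe is deliberately simple and robust for censored single-cell
qPCR data: a two-sided Wilcoxon-Mann-Whitney rank-sum test per gene,
Benjamini-Hochberg adjustment across all tested genes, and a log fold
change defined as the difference of group medians of log2 expression
(group A minus group B).  A gene is called differential only under the
dual criterion adjusted p < alpha AND |LFC| >= lfc_min.

Test mode: for small untied samples (n + m <= exact_threshold, default
20) the exact permutation null is used; otherwise the tie-corrected
normal approximation with continuity correction.  Both are exposed via
``mode``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ExpressionMatrix

__all__ = ["rank_sum_test", "bh_adjust", "log_fold_change", "differential_genes"]

EXACT_THRESHOLD = 20


def rank_sum_test(x, y, mode: str = "auto", exact_threshold: int = EXACT_THRESHOLD):
    """Two-sided Wilcoxon-Mann-Whitney test.

    Returns (U statistic of the first sample, two-sided p).  ``mode`` is
    one of ``auto`` (exact for small untied samples, else asymptotic),
    ``exact`` or ``asymptotic``.  Samples with no variation at all
    (every value identical in both groups) are perfectly exchangeable and
    get p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(combined).size < combined.size
    if mode == "auto":
        method = "exact" if (combined.size <= exact_threshold and not has_ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"mode must be auto/exact/asymptotic, got {mode!r}")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def log_fold_change(x, y) -> float:
    """Difference of medians of log2 expression, first group minus second."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    return float(np.median(x) - np.median(y))


def differential_genes(expr: ExpressionMatrix, group_a, group_b,
                       alpha: float = 1e-5, lfc_min: float = 2.0,
                       mode: str = "auto",
                       exact_threshold: int = EXACT_THRESHOLD) -> pd.DataFrame:
    """Per-gene rank-sum test between two disjoint cell groups.

    BH adjustment is applied across every gene in the matrix (the whole
    tested family).  Output is sorted by adjusted p ascending, then |LFC|
    descending; ``significant`` marks genes meeting the dual criterion.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap, key=str)[:5]}")
    for c in group_a + group_b:
        if c not in expr.data.index:
            raise KeyError(f"unknown cell: {c!r}")

    A = expr.data.loc[group_a]
    B = expr.data.loc[group_b]
    genes = list(expr.data.columns)
    n, m = len(group_a), len(group_b)
    Av, Bv = A.to_numpy(dtype=float), B.to_numpy(dtype=float)
    lfcs = list(np.median(Av, axis=0) - np.median(Bv, axis=0))
    if mode == "asymptotic" or (mode == "auto" and n + m > exact_threshold):
        # one vectorised call; identical to the per-gene asymptotic path
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.mannwhitneyu(Av, Bv, alternative="two-sided",
                                     method="asymptotic", use_continuity=True,
                                     axis=0)
        stats_ = np.asarray(res.statistic, dtype=float)
        pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
        # genes with no variation at all are perfectly exchangeable
        flat = np.ptp(np.vstack([Av, Bv]), axis=0) == 0
        stats_[flat] = n * m / 2.0
        pvals[flat] = 1.0
        stats_, pvals = list(stats_), list(pvals)
    else:
        stats_, pvals = [], []
        for j in range(len(genes)):
            u, p = rank_sum_test(Av[:, j], Bv[:, j],
                                 mode=mode, exact_threshold=exact_threshold)
            stats_.append(u)
            pvals.append(p)
    padj = bh_adjust(pvals)
    out = pd.DataFrame(
        {
            "gene": genes,
            "statistic": stats_,
            "p": pvals,
            "p_adj": padj,
            "lfc": lfcs,
        }
    )
    out["significant"] = (out["p_adj"] < alpha) & (out["lfc"].abs() >= lfc_min)
    out = out.sort_values(
        ["p_adj", "lfc"], key=lambda s: s.abs() if s.name == "lfc" else s,
        ascending=[True, False], kind="stable",
    ).reset_index(drop=True)
    return out
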