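"""Weighted gene co-expression networks, one per cell subset.

Construction follows the unsigned weighted-network recipe: Pearson
correlation on linear-scale expression, power adjacency
a_ij = |cor(x_i, x_j)|^beta, a soft threshold beta chosen as the smallest
exponent for which the connectivity distribution approximates a power
law (scale-free fit R^2 above a threshold, 0.85 by default), topological
overlap (TOM) as the similarity for module detection, and average-linkage
clustering of 1 - TOM with a deterministic static cut: the dendrogram is
cut at a quantile of its merge heights and clusters below a minimum size
are left unassigned (label 0).  The static cut replaces the usual dynamic
tree-cut heuristic with a testable, tunable rule; module boundaries will
therefore not match dynamic-cut output gene for gene.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import average_linkage
from .preprocess import ExpressionMatrix, to_linear

logger = logging.getLogger(__name__)

__all__ = [
    "CoexprNetwork",
    "ModuleOverlap",
    "NoQualifyingBetaError",
    "pearson_matrix",
    "power_adjacency",
    "connectivity",
    "scale_free_fit",
    "choose_beta",
    "topological_overlap",
    "detect_modules",
    "build_network",
    "module_overlap",
]


class NoQualifyingBetaError(ValueError):
    """No candidate soft threshold reached the scale-free fit target.

    Carries the full (beta, R^2) scan table so the caller can inspect and
    possibly relax the threshold.
    """

    def __init__(self, message: str, scan: pd.DataFrame):
        super().__init__(message)
        self.scan = scan


def pearson_matrix(expr) -> pd.DataFrame:
    """Gene-gene Pearson correlation of a (linear-scale) expression matrix."""
    data = expr.data if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    X = data.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [data.columns[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance genes present (filter first): {bad[:10]}")
    cor = np.clip(np.corrcoef(X, rowvar=False), -1.0, 1.0)
    cor = (cor + cor.T) / 2.0
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=data.columns, columns=data.columns)


def _as_square(mat) -> tuple[np.ndarray, list]:
    if isinstance(mat, pd.DataFrame):
        return mat.to_numpy(dtype=float), list(mat.index)
    arr = np.asarray(mat, dtype=float)
    return arr, list(range(arr.shape[0]))


def power_adjacency(cor, beta: int) -> pd.DataFrame:
    """Unsigned power adjacency |cor|^beta; diagonal fixed at 1."""
    if not float(beta).is_integer() or beta < 1:
        raise ValueError(f"beta must be an integer >= 1, got {beta}")
    c, ids = _as_square(cor)
    a = np.abs(c) ** int(beta)
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=ids, columns=ids)


def connectivity(adjacency) -> pd.Series:
    """Whole-network connectivity k_i = sum of off-diagonal adjacency per gene."""
    a, ids = _as_square(adjacency)
    k = a.sum(axis=1) - np.diag(a)
    return pd.Series(k, index=ids, name="k")


def scale_free_fit(k, n_bins: int = 10) -> float:
    """Scale-free topology fit index R^2 of the connectivity distribution.

    Connectivities are binned into ``n_bins`` equal-width bins, empty bins
    dropped, and R^2 computed as the squared Pearson correlation between
    log10 of the bin frequency p(k) and log10 of the mean connectivity in
    the bin.
    """
    k = np.asarray(pd.Series(k), dtype=float)
    if np.ptp(k) == 0:
        raise ValueError("all connectivities identical; scale-free fit undefined")
    edges = np.histogram_bin_edges(k, bins=n_bins)
    which = np.digitize(k, edges[1:-1])
    counts = np.bincount(which, minlength=n_bins)
    mean_k = np.array([k[which == b].mean() if counts[b] else np.nan
                       for b in range(n_bins)])
    keep = counts > 0
    pk = counts[keep] / counts.sum()
    mk = mean_k[keep]
    positive = mk > 0
    if positive.sum() < keep.sum():
        warnings.warn("bins with non-positive mean connectivity dropped from the fit")
    pk, mk = pk[positive], mk[positive]
    if pk.size < 2:
        raise ValueError("fewer than 2 usable bins; cannot fit")
    if pk.size == 2:
        warnings.warn("only 2 usable bins; R^2 = 1 degenerately")
        return 1.0
    if np.ptp(np.log10(pk)) == 0 or np.ptp(np.log10(mk)) == 0:
        # a perfectly flat log-frequency profile carries no power-law signal
        return 0.0
    r = np.corrcoef(np.log10(pk), np.log10(mk))[0, 1]
    return float(r ** 2)


def choose_beta(cor, candidates=range(1, 21), r2_threshold: float = 0.85,
                n_bins: int = 10):
    """Smallest soft-threshold exponent with scale-free fit above threshold.

    Returns (beta, R^2, scan) where scan tabulates R^2 for every candidate
    tried (the scan stops at the first qualifying beta; later rows are
    NaN).  Raises :class:`NoQualifyingBetaError` carrying the full scan if
    no candidate qualifies.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    rows = []
    chosen = None
    for b in candidates:
        adj = power_adjacency(cor, b)
        k = connectivity(adj)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = np.nan
        rows.append({"beta": b, "r2": r2})
        if np.isfinite(r2) and r2 > r2_threshold:
            chosen = (int(b), float(r2))
            break
    scan = pd.DataFrame(rows)
    if chosen is None:
        raise NoQualifyingBetaError(
            f"no candidate beta reached R^2 > {r2_threshold}", scan
        )
    return chosen[0], chosen[1], scan


def topological_overlap(adjacency) -> pd.DataFrame:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    for i != j, and TOM_ii = 1.  High overlap means two genes share most of
    their network neighbourhood.
    """
    a, ids = _as_square(adjacency)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if (a < -1e-12).any() or (a > 1 + 1e-12).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    # L_ij = sum_{u != i,j} a_iu a_uj = (A@A)_ij - a_ii*a_ij - a_ij*a_jj
    L = a @ a - np.diag(a)[:, None] * a - a * np.diag(a)[None, :]
    numer = L + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(denom, 1.0)  # diagonal is overwritten below
    if (denom <= 0).any():
        raise ValueError("non-positive TOM denominator; adjacency is invalid")
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=ids, columns=ids)


def detect_modules(tom, min_module_size: int = 10,
                   cut_quantile: float = 0.99) -> pd.Series:
    """Modules from average-linkage clustering of TOM dissimilarity.

    The dendrogram of 1 - TOM is cut at the ``cut_quantile`` quantile of
    its merge heights; resulting clusters smaller than
    ``min_module_size`` are unassigned (label 0).  Modules are numbered
    1, 2, ... by decreasing size.
    """
    t, ids = _as_square(tom)
    n = t.shape[0]
    if n < min_module_size:
        warnings.warn(
            f"only {n} genes (< min_module_size={min_module_size}); all unassigned"
        )
        return pd.Series(0, index=ids, name="module")
    dissim = 1.0 - t
    np.fill_diagonal(dissim, 0.0)
    dend = average_linkage(pd.DataFrame(dissim, index=ids, columns=ids))
    thresh = float(np.quantile(dend.heights, cut_quantile))
    flat = dend.cut(thresh)
    sizes = flat.value_counts()
    keep = sizes[sizes >= min_module_size]
    # number modules by decreasing size; ties by first appearance for determinism
    ordered = sorted(keep.index, key=lambda c: (-keep[c], int(np.nonzero(flat.to_numpy() == c)[0][0])))
    relabel = {c: i + 1 for i, c in enumerate(ordered)}
    labels = flat.map(lambda c: relabel.get(c, 0)).astype(int)
    return labels.rename("module")


@dataclass
class CoexprNetwork:
    """One weighted co-expression network and its intermediates."""

    gene_ids: list
    correlation: pd.DataFrame
    beta: int
    adjacency: pd.DataFrame
    connectivity: pd.Series
    scale_free_r2: float
    tom: pd.DataFrame
    modules: pd.Series
    beta_scan: pd.DataFrame | None = None
    dropped_genes: list = field(default_factory=list)

    def module_genes(self, module: int) -> list:
        return list(self.modules.index[self.modules == module])

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.adjacency.to_csv(path / "adjacency.csv")
        self.tom.to_csv(path / "tom.csv")
        self.modules.rename("module").to_csv(path / "modules.csv", index_label="gene")
        meta = pd.DataFrame(
            {"beta": [self.beta], "scale_free_r2": [self.scale_free_r2],
             "n_genes": [len(self.gene_ids)],
             "n_dropped": [len(self.dropped_genes)]}
        )
        meta.to_csv(path / "network.csv", index=False)
        if self.beta_scan is not None:
            self.beta_scan.to_csv(path / "beta_scan.csv", index=False)


def build_network(expr: ExpressionMatrix, cells=None, beta: int | None = None,
                  r2_threshold: float = 0.85, beta_candidates=range(1, 21),
                  n_bins: int = 10, min_module_size: int = 10,
                  cut_quantile: float = 0.99, var_tol: float = 0.0) -> CoexprNetwork:
    """Full network construction for one cell subset.

    Log2 input is anti-logged to the linear scale first.  Genes with no
    variance across the subset (plus any below ``var_tol``) are dropped
    with a log entry before correlation.  ``beta`` fixes the soft
    threshold; when None, ``choose_beta`` scans for the smallest exponent
    whose fit exceeds ``r2_threshold``.
    """
    if cells is not None:
        expr = expr.subset_cells(cells)
    if expr.data.shape[0] < 3:
        raise ValueError("need at least 3 cells to build a network")
    lin = to_linear(expr) if expr.scale == "log2" else expr
    sd = lin.data.std(axis=0, ddof=0)
    dropped = list(sd.index[sd <= var_tol])
    if dropped:
        logger.info("dropping %d zero/low-variance genes: %s%s",
                    len(dropped), dropped[:10], "..." if len(dropped) > 10 else "")
    kept = lin.data.drop(columns=dropped)
    cor = pearson_matrix(kept)

    scan = None
    if beta is None:
        beta, r2, scan = choose_beta(cor, candidates=beta_candidates,
                                     r2_threshold=r2_threshold, n_bins=n_bins)
        adj = power_adjacency(cor, beta)
        k = connectivity(adj)
    else:
        adj = power_adjacency(cor, beta)
        k = connectivity(adj)
        try:
            r2 = scale_free_fit(k, n_bins=n_bins)
        except ValueError:
            r2 = float("nan")
    tom = topological_overlap(adj)
    modules = detect_modules(tom, min_module_size=min_module_size,
                             cut_quantile=cut_quantile)
    return CoexprNetwork(
        gene_ids=list(cor.index), correlation=cor, beta=int(beta),
        adjacency=adj, connectivity=k, scale_free_r2=float(r2),
        tom=tom, modules=modules, beta_scan=scan, dropped_genes=dropped,
    )


@dataclass
class ModuleOverlap:
    """Gene-membership comparison between the modules of two networks."""

    table: pd.DataFrame        # module_a, module_b, size_a, size_b, n_shared, jaccard, frac_a_in_b
    shared_genes: dict         # (module_a, module_b) -> sorted gene list


def module_overlap(net_a, net_b) -> ModuleOverlap:
    """Pairwise overlap between assigned modules of two networks.

    Accepts CoexprNetwork objects or bare gene->module label Series.
    Label 0 (unassigned) is excluded.  ``frac_a_in_b`` is the share of
    the A-module contained in the B-module.
    """
    la = net_a.modules if isinstance(net_a, CoexprNetwork) else pd.Series(net_a)
    lb = net_b.modules if isinstance(net_b, CoexprNetwork) else pd.Series(net_b)
    rows, shared = [], {}
    mods_a = sorted(int(m) for m in la.unique() if m != 0)
    mods_b = sorted(int(m) for m in lb.unique() if m != 0)
    for ma in mods_a:
        genes_a = set(la.index[la == ma])
        for mb in mods_b:
            genes_b = set(lb.index[lb == mb])
            inter = genes_a & genes_b
            union = genes_a | genes_b
            rows.append({
                "module_a": ma, "module_b": mb,
                "size_a": len(genes_a), "size_b": len(genes_b),
                "n_shared": len(inter),
                "jaccard": len(inter) / len(union) if union else 0.0,
                "frac_a_in_b": len(inter) / len(genes_a) if genes_a else 0.0,
            })
            shared[(ma, mb)] = sorted(inter, key=str)
    table = pd.DataFrame(rows, columns=["module_a", "module_b", "size_a",
                                        "size_b", "n_shared", "jaccard",
                                        "frac_a_in_b"])
    return ModuleOverlap(table=table, shared_genes=shared)
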