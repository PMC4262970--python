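"""Hierarchical clustering on correlation distance.

This is the dendrogram engine used both for unsupervised clustering of
cells and, downstream, for gene-module detection on topological-overlap
dissimilarity.  Average linkage (UPGMA) is implemented directly so that
ties in the merge order have a declared, reproducible resolution: among
equally close pairs the lexicographically smallest pair of cluster
indices (original leaves 0..n-1, then n, n+1, ... for merged clusters,
as in the SciPy linkage encoding) is merged first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .preprocess import ExpressionMatrix

__all__ = ["Dendrogram", "correlation_distance", "average_linkage"]


def correlation_distance(expr, axis: str = "cells") -> pd.DataFrame:
    """Pearson-correlation distance, d = 1 - cor, between cells or genes.

    Parameters
    ----------
    expr : ExpressionMatrix or DataFrame
        Cells x genes matrix.
    axis : {"cells", "genes"}
        Which axis to compute distances between.  ``cells`` correlates the
        row vectors (profiles over genes); ``genes`` the column vectors.

    Zero-variance vectors have undefined correlations and are rejected by
    name; filter them out first.
    """
    data = expr.data if isinstance(expr, ExpressionMatrix) else pd.DataFrame(expr)
    if axis == "cells":
        mat, ids = data.to_numpy(dtype=float), list(data.index)
    elif axis == "genes":
        mat, ids = data.to_numpy(dtype=float).T, list(data.columns)
    else:
        raise ValueError(f"axis must be 'cells' or 'genes', got {axis!r}")
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 observations per vector")
    sd = mat.std(axis=1)
    if (sd == 0).any():
        bad = [ids[i] for i in np.nonzero(sd == 0)[0]]
        raise ValueError(f"zero-variance vectors (undefined correlation): {bad}")
    cor = np.corrcoef(mat)
    d = 1.0 - np.clip(cor, -1.0, 1.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


@dataclass
class Dendrogram:
    """Average-linkage merge tree in the SciPy linkage encoding.

    ``linkage`` is the (n-1, 4) matrix of [cluster_i, cluster_j, height,
    size]; ``labels`` names the leaves in input order.
    """

    linkage: np.ndarray
    labels: list = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return self.linkage.shape[0] + 1

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_order(self) -> list:
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    def cut(self, height: float) -> pd.Series:
        """Flat clusters obtained by merging everything at or below ``height``."""
        flat = sch.fcluster(self.linkage, t=height, criterion="distance")
        return pd.Series(flat, index=self.labels, name="cluster")

    def cut_k(self, k: int) -> pd.Series:
        flat = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return pd.Series(flat, index=self.labels, name="cluster")

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage,
            columns=["cluster_i", "cluster_j", "height", "size"],
        ).astype({"cluster_i": int, "cluster_j": int, "size": int})

    def to_csv(self, path) -> None:
        self.merge_table().to_csv(path, index=False)

    def to_newick(self) -> str:
        """Ultrametric Newick string; leaf depth equals half the root height."""
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        node = {i: str(self.labels[i]) for i in range(n)}
        for step, (i, j, h, _) in enumerate(self.linkage):
            i, j = int(i), int(j)
            bi = h / 2.0 - height[i] / 2.0
            bj = h / 2.0 - height[j] / 2.0
            node[n + step] = f"({node[i]}:{bi:.10g},{node[j]}:{bj:.10g})"
            height[n + step] = h
        return node[n + self.linkage.shape[0] - 1] + ";"


def _validate_dissimilarity(d: np.ndarray) -> None:
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity must have a zero diagonal")
    if (d < -1e-12).any():
        raise ValueError("dissimilarity must be non-negative")


def average_linkage(dissim) -> Dendrogram:
    """UPGMA clustering of a dissimilarity matrix.

    Implements the Lance-Williams average-linkage update directly.  Ties
    are broken by the lexicographically smallest (cluster_i, cluster_j)
    pair, which makes the merge sequence fully deterministic.
    """
    if isinstance(dissim, pd.DataFrame):
        labels = list(dissim.index)
        d = dissim.to_numpy(dtype=float)
    else:
        d = np.asarray(dissim, dtype=float)
        labels = list(range(d.shape[0]))
    _validate_dissimilarity(d)
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")

    d = d.copy()
    np.fill_diagonal(d, np.inf)
    cluster_id = np.arange(n)          # current cluster id occupying each slot
    sizes = np.ones(n)
    active = np.ones(n, dtype=bool)
    Z = np.zeros((n - 1, 4))

    for step in range(n - 1):
        sub = np.where(active)[0]
        block = d[np.ix_(sub, sub)]
        m = block.min()
        # tie-break: smallest (id_i, id_j) among all pairs attaining the minimum
        ti, tj = np.nonzero(np.isclose(block, m, rtol=0.0, atol=0.0))
        best = None
        for a, b in zip(ti, tj):
            if a >= b:
                continue
            pair = tuple(sorted((int(cluster_id[sub[a]]), int(cluster_id[sub[b]]))))
            if best is None or pair < best[0]:
                best = (pair, sub[a], sub[b])
        (ci, cj), si, sj = best
        if cluster_id[si] > cluster_id[sj]:
            si, sj = sj, si
        Z[step] = [ci, cj, m, sizes[si] + sizes[sj]]
        # merged cluster stored in slot si; average-linkage update
        ni, nj = sizes[si], sizes[sj]
        new_row = (ni * d[si] + nj * d[sj]) / (ni + nj)
        d[si, :] = new_row
        d[:, si] = new_row
        d[si, si] = np.inf
        active[sj] = False
        d[sj, :] = np.inf
        d[:, sj] = np.inf
        sizes[si] = ni + nj
        cluster_id[si] = n + step

    return Dendrogram(linkage=Z, labels=labels)
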