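"""Synthetic single-cell qPCR datasets with planted ground truth.

The generator emulates the data regime of a multiplex single-cell qPCR
study of a leukemic bone marrow: a reference hierarchy tree of cell
clusters with per-node centroid profiles, cells scattered around their
node centroid with Gaussian noise in log2 space, censoring at a
background Ct, two leukemic branches carrying planted differentially
expressed genes, and latent-factor co-expression modules.

Design of the planted truth (all deliberate, so that every recovery
metric is exactly 1.0 in the noise-free limit rather than merely close):

* the two leukemic branches are *matched twins* — the second branch
  copies the first branch's topology and centroid draws — so the planted
  DE genes are the only systematic difference between the two compared
  groups;
* the planted DE shift is baked into the first leukemic branch's node
  centroids, and the DE genes are drawn from the mapping panel (as in
  real data, where a receptor such as Kit is both a lineage marker and a
  top differential gene); this keeps the twin branches separable by
  nearest-centroid mapping;
* co-expression module genes do not drift along the tree: they follow a
  lineage-independent latent-factor model, gene = baseline +
  loading * z_cell + noise, which yields controllable pairwise
  correlations of about loading^2 / (loading^2 + noise_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CtMatrix, ct_to_expression
from .reference_map import MappingResult, ReferenceTree, _all_steps

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_tree",
    "generate_cells",
    "generate_dataset",
    "truth_metrics",
]

BRANCH_NORMAL = "normal"
BRANCH_L1 = "leukemia_1"
BRANCH_L2 = "leukemia_2"


@dataclass
class SyntheticSpec:
    """Full description of one synthetic dataset; one seed drives everything."""

    n_nodes: int = 56
    n_genes: int = 175
    panel_size: int = 33
    cells_per_node: int = 20
    centroid_drift_sd: float = 0.5   # log2 units per tree edge
    noise_sd: float = 1.0            # log2 units per cell
    background_ct: float = 28.0
    leukemia_branch_nodes: int = 5   # nodes per leukemic branch (two branches)
    n_de_genes: int = 14
    de_shift: float = 4.0            # log2 units added in leukemia_1
    module_sizes: tuple = (20, 15)
    module_loading: float = 1.0
    factor_sd: float = 1.0
    baseline_low: float = 2.0
    baseline_high: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if min(self.centroid_drift_sd, self.noise_sd, self.factor_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.background_ct <= 0:
            raise ValueError("background_ct must be positive")
        if not (0 < self.panel_size <= self.n_genes):
            raise ValueError("panel_size must be in 1..n_genes")
        if self.n_de_genes > self.panel_size:
            raise ValueError("n_de_genes cannot exceed panel_size (DE genes are markers)")
        if self.panel_size + sum(self.module_sizes) > self.n_genes:
            raise ValueError("panel + module genes exceed the gene universe")

    @property
    def has_leukemia_branches(self) -> bool:
        return (self.leukemia_branch_nodes >= 1
                and self.n_nodes >= 2 * self.leukemia_branch_nodes + 1)

    # --- deterministic gene role allocation -------------------------------
    @property
    def gene_ids(self) -> list:
        width = len(str(self.n_genes))
        return [f"g{i + 1:0{width}d}" for i in range(self.n_genes)]

    @property
    def panel_genes(self) -> list:
        return self.gene_ids[: self.panel_size]

    @property
    def de_genes(self) -> list:
        if not self.has_leukemia_branches:
            return []
        return self.gene_ids[: self.n_de_genes]

    @property
    def module_genes(self) -> list:
        """Per planted module, the list of member genes."""
        out, start = [], self.panel_size
        for size in self.module_sizes:
            out.append(self.gene_ids[start: start + size])
            start += size
        return out

    @property
    def drift_genes(self) -> list:
        flat = {g for mod in self.module_genes for g in mod}
        return [g for g in self.gene_ids if g not in flat]


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated Ct matrix."""

    cells: pd.DataFrame   # index cell_id; true_node, true_branch, phenotype
    genes: pd.DataFrame   # index gene; in_panel, is_de, de_shift, module

    def to_csv(self, cells_path, genes_path) -> None:
        c = self.cells.copy()
        c.index.name = "cell_id"
        c.to_csv(cells_path)
        g = self.genes.copy()
        g.index.name = "gene"
        g.to_csv(genes_path)


@dataclass
class SyntheticDataset:
    ct: CtMatrix
    tree: ReferenceTree
    truth: SyntheticTruth

    @property
    def annotations(self) -> pd.Series:
        return self.truth.cells["phenotype"]


def _clamp(values: np.ndarray, background: float) -> np.ndarray:
    return np.clip(values, 0.0, background - 1e-6)


def generate_tree(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> ReferenceTree:
    """Random reference tree with drifting centroids and twin leukemic branches.

    The trunk grows by sequential random-parent attachment from a root
    whose profile is drawn uniformly; each child's centroid equals its
    parent's plus Gaussian drift on the lineage-informative (non-module)
    genes, clamped to [0, background).  The two leukemic branches are
    matched twins attached to the same trunk node, after which the
    planted DE shift is added to the first branch's centroids.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    n_genes = spec.n_genes
    drift_mask = np.isin(genes, spec.drift_genes)

    branch_n = spec.leukemia_branch_nodes if spec.has_leukemia_branches else 0
    trunk_n = spec.n_nodes - 2 * branch_n

    centroids = np.zeros((spec.n_nodes, n_genes))
    edges: list = []
    branch: dict = {}

    centroids[0] = rng.uniform(spec.baseline_low, spec.baseline_high, n_genes)
    branch[0] = BRANCH_NORMAL
    for i in range(1, trunk_n):
        parent = int(rng.integers(0, i))
        drift = np.where(drift_mask, rng.normal(0.0, spec.centroid_drift_sd, n_genes), 0.0)
        centroids[i] = _clamp(centroids[parent] + drift, spec.background_ct)
        edges.append((parent, i))
        branch[i] = BRANCH_NORMAL

    if branch_n:
        attach = int(rng.integers(0, trunk_n))
        a0 = trunk_n                      # first node of leukemia branch 1
        b0 = trunk_n + branch_n           # first node of leukemia branch 2
        local_parent = np.zeros(branch_n, dtype=int)
        for j in range(branch_n):
            if j == 0:
                parent = attach
            else:
                local_parent[j] = int(rng.integers(0, j))
                parent = a0 + local_parent[j]
            drift = np.where(drift_mask,
                             rng.normal(0.0, spec.centroid_drift_sd, n_genes), 0.0)
            centroids[a0 + j] = _clamp(centroids[parent] + drift, spec.background_ct)
            edges.append((parent, a0 + j))
            branch[a0 + j] = BRANCH_L1
        # twin branch: same topology, same centroid values, same attachment
        for j in range(branch_n):
            centroids[b0 + j] = centroids[a0 + j]
            parent = attach if j == 0 else b0 + local_parent[j]
            edges.append((parent, b0 + j))
            branch[b0 + j] = BRANCH_L2
        # planted DE shift lives in the leukemia_1 centroids
        de_mask = np.isin(genes, spec.de_genes)
        centroids[a0: a0 + branch_n, de_mask] = _clamp(
            centroids[a0: a0 + branch_n, de_mask] + spec.de_shift, spec.background_ct
        )

    table = pd.DataFrame(centroids, index=range(spec.n_nodes), columns=genes)
    return ReferenceTree(centroids=table, edges=edges, branch=branch)


_PHENO_P = {
    # P(Kit+), P(CD24-) per leukemic branch; chosen to echo the reported
    # immunophenotype composition of the aggressive subtype (97% Kit+, 72% CD24-)
    BRANCH_L1: (0.97, 0.72),
    BRANCH_L2: (0.40, 0.25),
}


def generate_cells(tree: ReferenceTree, spec: SyntheticSpec,
                   rng: np.random.Generator | None = None) -> tuple[CtMatrix, SyntheticTruth]:
    """Cells around node centroids, emitted as a censored Ct matrix plus truth.

    cell log2 value = centroid + Gaussian(noise_sd) + module loading * z_cell
    for module genes; values are converted to Ct = background - value with
    censoring handled in Ct space, so round-tripping through the
    preprocessing clamp reproduces max(0, value).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    genes = spec.gene_ids
    nodes = list(tree.centroids.index)
    n_cells = len(nodes) * spec.cells_per_node
    width = len(str(n_cells))
    cell_ids = [f"cell_{i + 1:0{width}d}" for i in range(n_cells)]
    true_node = np.repeat(nodes, spec.cells_per_node)

    values = tree.centroids.loc[true_node, genes].to_numpy(dtype=float)
    values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    for mod_genes in spec.module_genes:
        z = rng.normal(0.0, spec.factor_sd, n_cells)
        idx = [genes.index(g) for g in mod_genes]
        values[:, idx] += spec.module_loading * z[:, None]

    ct_vals = spec.background_ct - np.minimum(values, spec.background_ct - 1e-6)
    ct = CtMatrix(pd.DataFrame(ct_vals, index=cell_ids, columns=genes),
                  background_ct=spec.background_ct)

    true_branch = pd.Series(true_node, index=cell_ids).map(tree.branch)
    pheno = []
    for b in true_branch:
        if b in _PHENO_P:
            p_kit, p_cd24neg = _PHENO_P[b]
            kit = "Kit+" if rng.random() < p_kit else "Kit-"
            cd24 = "CD24-" if rng.random() < p_cd24neg else "CD24+"
            pheno.append(kit + cd24)
        else:
            pheno.append("normal")
    cells = pd.DataFrame(
        {"true_node": true_node, "true_branch": true_branch.to_numpy(),
         "phenotype": pheno},
        index=cell_ids,
    )

    module_label = pd.Series(0, index=genes, dtype=int)
    for mi, mod_genes in enumerate(spec.module_genes, start=1):
        module_label[mod_genes] = mi
    gene_truth = pd.DataFrame(
        {
            "in_panel": [g in set(spec.panel_genes) for g in genes],
            "is_de": [g in set(spec.de_genes) for g in genes],
            "de_shift": [spec.de_shift if g in set(spec.de_genes) else 0.0
                         for g in genes],
            "module": module_label.to_numpy(),
        },
        index=genes,
    )
    return ct, SyntheticTruth(cells=cells, genes=gene_truth)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Tree plus cells from a single seed; byte-identical for equal specs."""
    rng = np.random.default_rng(spec.seed)
    tree = generate_tree(spec, rng=rng)
    ct, truth = generate_cells(tree, spec, rng=rng)
    return SyntheticDataset(ct=ct, tree=tree, truth=truth)


def truth_metrics(truth: SyntheticTruth, tree: ReferenceTree,
                  mapping: MappingResult | None = None,
                  subtypes: pd.Series | None = None,
                  de_table: pd.DataFrame | None = None,
                  modules: pd.Series | None = None,
                  max_steps: int = 2) -> dict:
    """Recovery report of pipeline outputs against the planted truth.

    Returns a flat dict; DE precision is NaN when nothing was flagged
    (reported gracefully rather than as a division error).  Module
    recovery is the best-match Jaccard of each planted module against the
    detected modules.
    """
    out: dict = {}
    if mapping is not None:
        df = mapping.assignments
        missing = [c for c in df.index if c not in truth.cells.index]
        if missing:
            raise ValueError(f"mapped cells unknown to the truth: {missing[:5]}")
        orig = truth.cells.loc[df.index, "true_node"]
        steps = _all_steps(tree, zip(df["node_id"], orig))
        out["mapping_exact"] = float((steps == 0).mean())
        out["mapping_within"] = float((steps <= max_steps).mean())
    if subtypes is not None:
        missing = [c for c in subtypes.index if c not in truth.cells.index]
        if missing:
            raise ValueError(f"labelled cells unknown to the truth: {missing[:5]}")
        want = truth.cells.loc[subtypes.index, "true_branch"]
        out["subtype_accuracy"] = float((subtypes.to_numpy() == want.to_numpy()).mean())
    if de_table is not None:
        planted = set(truth.genes.index[truth.genes["is_de"]])
        flagged = set(de_table.loc[de_table["significant"], "gene"])
        out["de_n_flagged"] = len(flagged)
        out["de_precision"] = (len(flagged & planted) / len(flagged)
                               if flagged else float("nan"))
        out["de_recall"] = (len(flagged & planted) / len(planted)
                            if planted else float("nan"))
    if modules is not None:
        planted_ids = sorted(m for m in truth.genes["module"].unique() if m != 0)
        detected = {m: set(modules.index[modules == m])
                    for m in modules.unique() if m != 0}
        jaccards = {}
        for m in planted_ids:
            genes_m = set(truth.genes.index[truth.genes["module"] == m])
            best = 0.0
            for dset in detected.values():
                u = genes_m | dset
                if u:
                    best = max(best, len(genes_m & dset) / len(u))
            jaccards[int(m)] = best
        out["module_jaccard"] = jaccards
        if jaccards:
            out["module_jaccard_min"] = min(jaccards.values())
    return out
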