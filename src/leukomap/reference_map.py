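"""Projection of single cells onto a reference hematopoietic-hierarchy tree.

The reference is a minimum-spanning-tree-style hierarchy of cell clusters
(nodes), each carrying a mean log2 expression profile (centroid) over a
reference gene set.  A cell is mapped to the node whose centroid is
nearest in Euclidean distance over a reduced gene panel — by default the
intersection of the data's genes with the reference genes.  Concordance
of a mapping with known original positions is summarised as the fraction
of cells landing exactly on, or within a small number of tree steps of,
their original node.  Panel sufficiency is assessed by repeating the
mapping over randomly resampled gene panels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceTree",
    "MappingResult",
    "ConcordanceSummary",
    "PanelValidation",
    "compute_node_centroids",
    "map_cells",
    "tree_distance",
    "concordance",
    "random_panel_validation",
    "assign_subtypes",
    "phenotype_crosstab",
]


@dataclass
class ReferenceTree:
    """Tree of cluster nodes with per-node centroid expression profiles.

    ``centroids`` is nodes x genes (log2 scale); ``edges`` is a list of
    unordered node pairs forming a tree; ``branch`` optionally labels each
    node with the lineage branch it belongs to (e.g. HSC, GMP,
    DC/macrophage, or leukemic subtype branches).
    """

    centroids: pd.DataFrame
    edges: list
    branch: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.centroids.index.duplicated().any():
            raise ValueError("duplicate node identifiers")
        g = nx.Graph()
        g.add_nodes_from(self.centroids.index)
        g.add_edges_from(self.edges)
        if set(g.nodes) != set(self.centroids.index):
            extra = set(g.nodes) - set(self.centroids.index)
            raise ValueError(f"edges refer to unknown nodes: {sorted(extra, key=str)}")
        if len(self.centroids) > 1 and not nx.is_tree(g):
            raise ValueError("edges must form a connected acyclic graph")
        self._graph = g

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def node_ids(self) -> list:
        return list(self.centroids.index)

    @property
    def gene_ids(self) -> list:
        return list(self.centroids.columns)

    @classmethod
    def from_csv(cls, nodes_path, edges_path) -> "ReferenceTree":
        nodes = pd.read_csv(nodes_path, index_col=0)
        nodes.index.name = None
        branch = {}
        if "branch" in nodes.columns:
            branch = nodes["branch"].to_dict()
            nodes = nodes.drop(columns=["branch"])
        edges_df = pd.read_csv(edges_path)
        edges = list(zip(edges_df.iloc[:, 0], edges_df.iloc[:, 1]))
        return cls(centroids=nodes, edges=edges, branch=branch)

    def to_csv(self, nodes_path, edges_path) -> None:
        out = self.centroids.copy()
        if self.branch:
            out.insert(0, "branch", [self.branch.get(n, "") for n in out.index])
        out.index.name = "node_id"
        out.to_csv(nodes_path)
        pd.DataFrame(self.edges, columns=["node_a", "node_b"]).to_csv(
            edges_path, index=False
        )

    @classmethod
    def from_json(cls, path) -> "ReferenceTree":
        with open(path) as fh:
            doc = json.load(fh)
        centroids = pd.DataFrame(
            doc["centroids"], index=doc["node_ids"], columns=doc["gene_ids"]
        )
        edges = [tuple(e) for e in doc["edges"]]
        branch = doc.get("branch", {})
        # JSON object keys are strings; map back onto the node-id dtype
        bynode = {n: branch[str(n)] for n in centroids.index if str(n) in branch}
        return cls(centroids=centroids, edges=edges, branch=bynode)

    def to_json(self, path) -> None:
        doc = {
            "node_ids": [int(n) if isinstance(n, (int, np.integer)) else n
                         for n in self.centroids.index],
            "gene_ids": list(self.centroids.columns),
            "centroids": self.centroids.to_numpy().tolist(),
            "edges": [[int(a) if isinstance(a, (int, np.integer)) else a,
                       int(b) if isinstance(b, (int, np.integer)) else b]
                      for a, b in self.edges],
            "branch": {str(k): v for k, v in self.branch.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


@dataclass
class MappingResult:
    """Per-cell node assignment with the distance at assignment."""

    assignments: pd.DataFrame  # index cell_id; columns node_id, distance [, original_node_id, subtype]
    panel: list = field(default_factory=list)

    @property
    def cell_ids(self) -> list:
        return list(self.assignments.index)

    def to_csv(self, path) -> None:
        out = self.assignments.copy()
        out.index.name = "cell_id"
        out.to_csv(path)


@dataclass
class ConcordanceSummary:
    fraction_exact: float
    fraction_within: float
    max_steps: int
    n_cells: int

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_exact <= self.fraction_within <= 1):
            raise ValueError("need 0 <= exact <= within <= 1")


@dataclass
class PanelValidation:
    summaries: list            # one ConcordanceSummary per random panel
    panels: list               # the gene lists drawn
    mean_exact: float
    mean_within: float


def compute_node_centroids(expr: ExpressionMatrix, node_assignment: pd.Series) -> pd.DataFrame:
    """Per-node arithmetic mean of log2 expression (nodes x genes)."""
    assignment = pd.Series(node_assignment)
    missing = [c for c in expr.cell_ids if c not in assignment.index]
    if missing:
        raise ValueError(f"cells without a node assignment: {missing[:5]}")
    labels = assignment.loc[expr.data.index]
    grouped = expr.data.groupby(labels.to_numpy()).mean()
    grouped.index.name = "node_id"
    return grouped


def map_cells(expr: ExpressionMatrix, tree: ReferenceTree, panel=None,
              original: pd.Series | None = None) -> MappingResult:
    """Assign each cell to the nearest node centroid over a gene panel.

    The panel defaults to the intersection of the data's genes with the
    reference gene set (kept in data-column order).  Ties in the minimum
    distance go to the lowest node_id.
    """
    if panel is None:
        ref = set(tree.gene_ids)
        panel = [g for g in expr.gene_ids if g in ref]
        logger.info("effective gene panel: %d shared genes", len(panel))
    panel = list(panel)
    if not panel:
        raise ValueError("effective gene panel is empty")
    bad = [g for g in panel if g not in expr.data.columns or g not in tree.centroids.columns]
    if bad:
        raise ValueError(f"panel genes absent from data or reference: {bad[:5]}")

    # order nodes by ascending node_id so argmin's first-hit rule == lowest id
    order = sorted(tree.node_ids)
    cent = tree.centroids.loc[order, panel].to_numpy(dtype=float)
    X = expr.data[panel].to_numpy(dtype=float)
    dist = cdist(X, cent, metric="euclidean")
    idx = dist.argmin(axis=1)
    assigned = [order[i] for i in idx]
    out = pd.DataFrame(
        {"node_id": assigned, "distance": dist[np.arange(len(idx)), idx]},
        index=expr.data.index,
    )
    if original is not None:
        orig = pd.Series(original)
        missing = [c for c in out.index if c not in orig.index]
        if missing:
            raise ValueError(f"cells without an original node: {missing[:5]}")
        out["original_node_id"] = orig.loc[out.index].to_numpy()
    return MappingResult(assignments=out, panel=panel)


def tree_distance(tree: ReferenceTree, a, b) -> int:
    """Number of edges on the unique path between nodes a and b."""
    for x in (a, b):
        if x not in tree.graph:
            raise KeyError(f"unknown node: {x!r}")
    return nx.shortest_path_length(tree.graph, a, b)


def _all_steps(tree: ReferenceTree, pairs) -> np.ndarray:
    lengths = dict(nx.all_pairs_shortest_path_length(tree.graph))
    return np.array([lengths[a][b] for a, b in pairs])


def concordance(mapping: MappingResult, tree: ReferenceTree, max_steps: int = 2) -> ConcordanceSummary:
    """Fraction of cells mapped exactly to / within ``max_steps`` of their original node."""
    df = mapping.assignments
    if "original_node_id" not in df.columns:
        raise ValueError("mapping carries no original node assignments")
    steps = _all_steps(tree, zip(df["node_id"], df["original_node_id"]))
    n = len(df)
    return ConcordanceSummary(
        fraction_exact=float((steps == 0).sum() / n),
        fraction_within=float((steps <= max_steps).sum() / n),
        max_steps=max_steps,
        n_cells=n,
    )


def random_panel_validation(expr: ExpressionMatrix, tree: ReferenceTree,
                            original: pd.Series, panel_size: int = 33,
                            n_lists: int = 100, max_steps: int = 2,
                            seed=None, rng=None) -> PanelValidation:
    """Concordance of the mapping under randomly resampled gene panels.

    Draws ``n_lists`` panels of ``panel_size`` genes uniformly without
    replacement from the genes shared between the data and the reference,
    maps all cells with each panel, and summarises concordance per panel
    and on average.  Fully reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ref = set(tree.gene_ids)
    shared = [g for g in expr.gene_ids if g in ref]
    if panel_size > len(shared):
        raise ValueError(
            f"panel_size {panel_size} exceeds the {len(shared)} shared genes"
        )
    summaries, panels = [], []
    for _ in range(n_lists):
        pick = rng.choice(len(shared), size=panel_size, replace=False)
        panel = [shared[i] for i in sorted(pick)]
        m = map_cells(expr, tree, panel=panel, original=original)
        summaries.append(concordance(m, tree, max_steps=max_steps))
        panels.append(panel)
    return PanelValidation(
        summaries=summaries,
        panels=panels,
        mean_exact=float(np.mean([s.fraction_exact for s in summaries])),
        mean_within=float(np.mean([s.fraction_within for s in summaries])),
    )


def assign_subtypes(mapping: MappingResult, tree: ReferenceTree,
                    branch_map: dict | None = None) -> pd.Series:
    """Label each cell with the branch of the node it mapped to."""
    if branch_map is None:
        branch_map = tree.branch
    nodes = mapping.assignments["node_id"]
    missing = sorted({n for n in nodes if n not in branch_map}, key=str)
    if missing:
        raise ValueError(f"mapped nodes missing from branch_map: {missing}")
    return nodes.map(branch_map).rename("subtype")


@dataclass
class CrosstabResult:
    counts: pd.DataFrame       # rows: phenotype, columns: subtype
    row_proportions: pd.DataFrame   # P(subtype | phenotype)
    col_proportions: pd.DataFrame   # P(phenotype | subtype)


def phenotype_crosstab(subtypes: pd.Series, phenotypes: pd.Series) -> CrosstabResult:
    """Cross-tabulate immunophenotype groups against mapped subtypes."""
    subtypes, phenotypes = pd.Series(subtypes), pd.Series(phenotypes)
    if set(subtypes.index) != set(phenotypes.index):
        raise ValueError("subtype and phenotype labelings cover different cells")
    phenotypes = phenotypes.loc[subtypes.index]
    counts = pd.crosstab(phenotypes, subtypes)
    counts.index.name, counts.columns.name = "phenotype", "subtype"
    return CrosstabResult(
        counts=counts,
        row_proportions=counts.div(counts.sum(axis=1), axis=0),
        col_proportions=counts.div(counts.sum(axis=0), axis=1),
    )
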