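"""End-to-end orchestration: simulate/ingest -> preprocess -> map -> subtype
-> differential expression -> co-expression networks -> module comparison.

Every stage output is persisted under the run directory and the run ends
with a machine-readable ``summary.json``.  All stages are pure functions
of (inputs, config), and every source of randomness flows from the single
config seed, so rerunning a config reproduces the summary byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, diffexpr, reference_map, synthetic
from .preprocess import CtMatrix, ct_to_expression
from .synthetic import BRANCH_L1, BRANCH_L2, SyntheticSpec

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_all"]

# Network cell subsets evaluated by default: each leukemic subtype alone,
# plus both pooled.
DEFAULT_SUBSETS = {
    "all_leukemia": [BRANCH_L1, BRANCH_L2],
    "leukemia_1": [BRANCH_L1],
    "leukemia_2": [BRANCH_L2],
}
# Fixed soft thresholds per subset; "auto" scans for the smallest
# qualifying exponent instead.
DEFAULT_BETAS = {"all_leukemia": 4, "leukemia_1": 5, "leukemia_2": 4}


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Either ``synthetic`` holds a :class:`synthetic.SyntheticSpec` (or a
    dict of its fields), or the ``ct_path`` / ``tree_nodes_path`` /
    ``tree_edges_path`` inputs must point at readable files.
    """

    synthetic: object = None
    ct_path: str | None = None
    tree_nodes_path: str | None = None
    tree_edges_path: str | None = None
    annotations_path: str | None = None
    original_nodes_path: str | None = None

    background_ct: float = 28.0
    panel: list | None = None          # None -> intersection of gene sets
    max_steps: int = 2
    panel_size: int = 33
    n_lists: int = 100

    de_group_a: str = BRANCH_L1
    de_group_b: str = BRANCH_L2
    alpha: float = 1e-5
    lfc_min: float = 2.0
    test_mode: str = "auto"

    network_subsets: dict = field(default_factory=lambda: dict(DEFAULT_SUBSETS))
    betas: dict = field(default_factory=lambda: dict(DEFAULT_BETAS))  # subset -> int | "auto"
    r2_threshold: float = 0.85
    n_bins: int = 10
    min_module_size: int = 10
    cut_quantile: float = 0.99

    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticSpec(**self.synthetic)

    def validate(self) -> None:
        if self.synthetic is None:
            for name in ("ct_path", "tree_nodes_path", "tree_edges_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"config requires {name} when no synthetic spec is given")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")
        for sub in self.betas:
            if sub not in self.network_subsets:
                raise ValueError(f"beta given for unknown network subset {sub!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        if dataclasses.is_dataclass(self.synthetic):
            doc["synthetic"] = dataclasses.asdict(self.synthetic)
            doc["synthetic"]["module_sizes"] = list(self.synthetic.module_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


def _round(x, nd=10):
    if isinstance(x, float):
        return round(x, nd)
    return x


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage, persist intermediates, return the summary dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}

    # --- inputs ----------------------------------------------------------
    truth = None
    annotations = None
    original = None
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        ds = synthetic.generate_dataset(spec)
        ct, tree, truth = ds.ct, ds.tree, ds.truth
        annotations = ds.annotations
        original = truth.cells["true_node"]
        ct.to_csv(out / "ct.csv")
        tree.to_csv(out / "nodes.csv", out / "edges.csv")
        truth.to_csv(out / "truth_cells.csv", out / "truth_genes.csv")
        annotations.rename("phenotype").to_csv(out / "annotations.csv",
                                               index_label="cell_id")
    else:
        ct = CtMatrix.from_csv(config.ct_path, background_ct=config.background_ct)
        tree = reference_map.ReferenceTree.from_csv(
            config.tree_nodes_path, config.tree_edges_path)
        if config.annotations_path:
            annotations = pd.read_csv(config.annotations_path, index_col=0).iloc[:, 0]
        if config.original_nodes_path:
            original = pd.read_csv(config.original_nodes_path, index_col=0).iloc[:, 0]

    # --- preprocess ------------------------------------------------------
    expr = ct_to_expression(ct)
    expr.to_csv(out / "expression.csv")
    summary["n_cells"] = len(expr.cell_ids)
    summary["n_genes"] = len(expr.gene_ids)

    # --- mapping ---------------------------------------------------------
    panel = config.panel
    if panel is None and config.synthetic is not None:
        # the generator's marker panel emulates the reduced shared gene set
        panel = config.synthetic.panel_genes
    mapping = reference_map.map_cells(expr, tree, panel=panel,
                                      original=original)
    summary["panel_n_genes"] = len(mapping.panel)

    if original is not None:
        conc = reference_map.concordance(mapping, tree, max_steps=config.max_steps)
        summary["concordance"] = {
            "fraction_exact": _round(conc.fraction_exact),
            "fraction_within": _round(conc.fraction_within),
            "max_steps": conc.max_steps,
            "n_cells": conc.n_cells,
        }
        pv = reference_map.random_panel_validation(
            expr, tree, original, panel_size=min(config.panel_size, len(mapping.panel)),
            n_lists=config.n_lists, max_steps=config.max_steps,
            seed=config.seed,
        )
        summary["panel_validation"] = {
            "mean_exact": _round(pv.mean_exact),
            "mean_within": _round(pv.mean_within),
            "n_lists": config.n_lists,
            "panel_size": min(config.panel_size, len(mapping.panel)),
        }

    # --- subtypes & phenotypes -------------------------------------------
    subtypes = reference_map.assign_subtypes(mapping, tree)
    mapping.assignments["subtype"] = subtypes
    mapping.to_csv(out / "mapping.csv")
    sizes = subtypes.value_counts().sort_index()
    summary["subtype_sizes"] = {str(k): int(v) for k, v in sizes.items()}

    if annotations is not None:
        xtab = reference_map.phenotype_crosstab(subtypes, annotations)
        xtab.counts.to_csv(out / "phenotype_crosstab.csv")
        summary["phenotype_crosstab"] = {
            str(p): {str(s): int(v) for s, v in row.items()}
            for p, row in xtab.counts.iterrows()
        }

    # --- differential expression -----------------------------------------
    cells_a = list(subtypes.index[subtypes == config.de_group_a])
    cells_b = list(subtypes.index[subtypes == config.de_group_b])
    de_table = None
    if cells_a and cells_b:
        de_table = diffexpr.differential_genes(
            expr, cells_a, cells_b, alpha=config.alpha,
            lfc_min=config.lfc_min, mode=config.test_mode,
        )
        de_table.to_csv(out / "de.csv", index=False)
        top = de_table.iloc[0]
        summary["de"] = {
            "group_a": config.de_group_a, "group_b": config.de_group_b,
            "n_a": len(cells_a), "n_b": len(cells_b),
            "n_significant": int(de_table["significant"].sum()),
            "top_gene": str(top["gene"]),
            "top_lfc": _round(float(top["lfc"])),
        }
    else:
        logger.warning("DE skipped: empty group (%s: %d cells, %s: %d cells)",
                       config.de_group_a, len(cells_a),
                       config.de_group_b, len(cells_b))

    # --- co-expression networks ------------------------------------------
    networks = {}
    summary["networks"] = {}
    for name, labels in config.network_subsets.items():
        cells = list(subtypes.index[subtypes.isin(labels)])
        if len(cells) < 3:
            logger.warning("network %s skipped: %d cells", name, len(cells))
            continue
        beta = config.betas.get(name, "auto")
        net = coexpr.build_network(
            expr, cells=cells,
            beta=None if beta == "auto" else int(beta),
            r2_threshold=config.r2_threshold, n_bins=config.n_bins,
            min_module_size=config.min_module_size,
            cut_quantile=config.cut_quantile,
        )
        net.to_dir(out / f"network_{name}")
        networks[name] = net
        msizes = net.modules[net.modules > 0].value_counts().sort_index()
        summary["networks"][name] = {
            "n_cells": len(cells),
            "beta": net.beta,
            "scale_free_r2": _round(net.scale_free_r2),
            "module_sizes": {str(int(k)): int(v) for k, v in msizes.items()},
            "n_unassigned": int((net.modules == 0).sum()),
        }

    names = list(networks)
    overlaps = []
    for i, na in enumerate(names):
        for nb in names[i + 1:]:
            ov = coexpr.module_overlap(networks[na], networks[nb])
            t = ov.table.copy()
            t.insert(0, "network_a", na)
            t.insert(1, "network_b", nb)
            overlaps.append(t)
    if overlaps:
        pd.concat(overlaps, ignore_index=True).to_csv(out / "module_overlap.csv",
                                                      index=False)

    # --- recovery against planted truth -----------------------------------
    if truth is not None:
        metrics = synthetic.truth_metrics(
            truth, tree, mapping=mapping, subtypes=subtypes,
            de_table=de_table,
            modules=networks["all_leukemia"].modules
            if "all_leukemia" in networks else None,
            max_steps=config.max_steps,
        )
        summary["truth_metrics"] = {
            k: ({str(kk): _round(vv) for kk, vv in v.items()}
                if isinstance(v, dict) else _round(v))
            for k, v in metrics.items()
        }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, allow_nan=True)
    return summary
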