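# leukomap

Single-cell qPCR analysis of leukemic heterogeneity: map individual cells
onto a reference hematopoietic-hierarchy tree, compare the resulting
leukemic subtypes by differential expression, and contrast their weighted
gene co-expression networks.

## The problem

Multiplex single-cell qPCR yields a cells × genes matrix of threshold
cycles (Ct), censored at a background level (28 cycles here): log2
expression is `max(0, 28 − Ct)`. Given such a matrix for leukemic and
normal bone-marrow cells, plus a reference hierarchy — a tree of cell
clusters (e.g. a 56-node SPADE tree of normal hematopoiesis), each node
with a mean expression profile — the pipeline answers three questions:

1. **Where does each cell sit in the hierarchy?** Each cell is assigned to
   the node whose centroid is nearest in Euclidean distance over the genes
   shared between data and reference (a 33-gene marker panel in the
   emulated setting). Mapping quality is summarised as the fraction of
   cells placed exactly on, or within ≤2 tree steps of, a known original
   position, and panel sufficiency is validated over 100 random 33-gene
   panels. Cells landing on distinct branches define leukemic subtypes.
2. **What distinguishes the subtypes?** Per gene, a two-sided
   Wilcoxon–Mann–Whitney test with Benjamini–Hochberg adjustment; the log
   fold change is the difference of group medians of log2 expression, and
   a gene is called differential only if `adjusted p < 1e-5` and
   `|LFC| ≥ 2`.
3. **Do the subtypes wire their genes differently?** Per cell subset, an
   unsigned weighted co-expression network: adjacency `a_ij = |cor_ij|^β`
   on linear-scale expression, with β the smallest exponent whose
   connectivity distribution approximates a power law (scale-free fit
   `R² > 0.85`) or a fixed per-subset value; gene modules from
   average-linkage clustering of topological-overlap dissimilarity
   `1 − TOM`; and module-membership overlap (shared genes, Jaccard)
   between networks.

A synthetic-data generator plants the ground truth for every stage —
tree-structured centroids, Ct censoring, two leukemic branches with
planted differential genes, latent-factor co-expression modules — so the
whole pipeline is validated end to end. See `docs/methods.md` for models,
defaults, and design choices.

## Worked example

```python
import leukomap as lm

spec = lm.SyntheticSpec(seed=1, noise_sd=1.0)      # 56 nodes, 175 genes
ds = lm.generate_dataset(spec)
expr = lm.ct_to_expression(ds.ct)
mapping = lm.map_cells(expr, ds.tree, panel=spec.panel_genes,
                       original=ds.truth.cells["true_node"])
conc = lm.concordance(mapping, ds.tree, max_steps=2)
print(f"mapped {conc.n_cells} cells: {conc.fraction_exact:.1%} exact, "
      f"{conc.fraction_within:.1%} within 2 steps")

subtypes = lm.assign_subtypes(mapping, ds.tree)
l1 = list(subtypes.index[subtypes == "leukemia_1"])
l2 = list(subtypes.index[subtypes == "leukemia_2"])
de = lm.differential_genes(expr, l1, l2, alpha=1e-5, lfc_min=2.0)
print(f"{de.significant.sum()} differential genes")

net1 = lm.build_network(expr, cells=l1, beta=5)
net2 = lm.build_network(expr, cells=l2, beta=4)
row = lm.module_overlap(net1, net2).table.sort_values(
    "n_shared", ascending=False).iloc[0]
print(f"largest overlap: {int(row.n_shared)} shared genes "
      f"(Jaccard {row.jaccard:.2f})")
```

prints

```
mapped 1120 cells: 82.9% exact, 97.1% within 2 steps
14 differential genes
largest overlap: 165 shared genes (Jaccard 0.95)
```

At the default per-cell noise (sd 1.0 log2 units), 83% of cells map back
to their exact generating node and 97% land within two tree steps; the 14
planted differential genes are recovered exactly (the top one with
LFC ≈ 4.3, matching the planted +4 shift); and the two subtype networks
share one large module. In the noise-free limit every recovery metric is
exactly 1.0.

The same stages are available from the shell:

```sh
leukomap simulate --seed 1 --out sim/
leukomap preprocess --ct sim/ct.csv --out expr.csv
leukomap map --expr expr.csv --tree-nodes sim/nodes.csv --tree-edges sim/edges.csv --out mapping.csv
leukomap run-all --seed 1 --out run/        # everything, plus summary.json
```

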