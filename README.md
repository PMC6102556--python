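# phylogrid

Grid-based spatial phylogenetics across multiple taxonomic groups:
observed diversity/endemism surfaces, a constrained-randomization
significance framework with CANAPE neo/paleo-endemism categories,
phylogenetic beta-diversity regionalization, and cross-taxon
concordance and fuzzy map-comparison layers.

`phylogrid` is aimed at biogeographers and conservation analysts who
have, per taxonomic group, (a) a rooted phylogeny with branch lengths
and (b) point occurrence records in an equal-area projection, and who
want to locate grid cells holding significantly more (or less)
evolutionary history than their richness predicts — and to ask whether
several groups agree about where those cells are.

## Metrics

Occurrences are aggregated onto square cells (default 25 km). With
`r_i` the range of taxon *i* in cells, and for each branch *b* of the
tree its length `L_b` and range `R_b` (number of cells holding at least
one descendant tip), the per-cell surfaces are

- **TR** — taxon richness;
- **WE** — weighted endemism, `Σ_i 1/r_i` over the cell's taxa;
- **PD** — phylogenetic diversity, `Σ L_b` over the branches on the
  union of tip-to-root paths of the cell's taxa;
- **PE** — phylogenetic endemism, `Σ L_b / R_b` over the same branches;
- **RPD / RPE** — PD or PE divided by the same quantity on a comparison
  tree with identical topology and all branches set to the mean length,
  flagging concentrations of unusually long (> 1) or short (< 1)
  branches.

Significance is assessed against a fixed-margin null model: taxa are
reassigned to cells at random while every cell keeps its richness and
every taxon keeps its range size, sampled by a curveball trade chain
(999 trials by default). Rank p-values use `(1 + count)/(1 + n_reps)`.
**CANAPE** then classifies each cell: step one screens for
significantly high PE (one-tailed, α = 0.05); step two splits passing
cells by the RPE ratio into *paleo* (significantly high — rare
long-branch lineages), *neo* (significantly low — rare short-branch
lineages), or *mixed*, upgraded to *super* when step one holds at
α = 0.01.

Between-cell structure uses **phylo-jaccard** dissimilarity (one minus
the shared fraction of branch length) with average-linkage clustering
into phylogenetic regions. Across groups, min-max standardized
surfaces are summarized as the mean over all cells and over
*concordant* cells (nonzero in every group), with leave-one-group-out
sensitivity, and groups are clustered by a neighborhood-tolerant fuzzy
similarity of their maps (200-km-diameter search circle by default).

A synthetic-data module (pure-birth trees, disc-shaped ranges with
lognormal radii, injectable neo/paleo endemism concentrations, and
exact-margin null datasets) makes the whole pipeline testable without
external data.

## Worked example

```python
import phylogrid as pg
from phylogrid.canape import (
    build_null_ensemble, canape_classify, significance_ranks,
)

tree = pg.simulate_tree(64, seed=7)
matrix = pg.simulate_occurrences(
    tree, pg.RangeModel(center_clustering=1.0), seed=7
)
print(f"{len(matrix.taxa)} taxa on {len(matrix.cell_ids)} cells")

# hide one rare, 10x-long-branch endemic in cell "10_5"
scenario = pg.EndemismScenario(
    kind="paleo", target_cells=frozenset(["10_5"]),
    n_taxa=1, branch_scale=10.0, range_cells=1,
)
tree2, matrix2 = pg.inject_endemism_scenario(tree, matrix, scenario, seed=7)

cfg = pg.RandomizationConfig(n_reps=999, seed=11)
ens = build_null_ensemble(matrix2, tree2, cfg)
cmap = canape_classify(
    significance_ranks(ens, "PE_actual", "high", 0.05),
    significance_ranks(ens, "PE_equalized", "high", 0.05),
    significance_ranks(ens, "RPE", "two", 0.05),
    cfg, either_tree=True,
)
print(cmap.counts().to_dict())
print("category at 10_5:", cmap.categories.loc["10_5"])
```

Output:

```
64 taxa on 173 cells
{'not-significant': 167, 'neo': 0, 'paleo': 1, 'mixed': 0, 'super': 5}
category at 10_5: paleo
```

The injected cell carries PE ≈ 14.0 against a landscape median of
0.27 (a single endemic branch contributes its full length), passes the
one-tailed PE screen, and its significantly high RPE ratio marks it as
paleo-endemism; the handful of super cells are where the clustered
ranges concentrate several range-restricted lineages at once.

The same analysis runs from the shell on real inputs:

```bash
phylogrid simulate --n-groups 3 --seed 4 data/       # or bring your own
phylogrid run-all config.yaml                        # full pipeline + manifest
```

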