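"""Phylogenetic beta-diversity: phylo-jaccard and average-linkage regions.

The phylo-jaccard index between two cells is one minus the fraction of
shared branch length: with A the summed length of branches present in
both cells and B, C the lengths unique to each, the dissimilarity is
(B + C) / (A + B + C).  Branch presence follows the same tips-to-root
convention as PD, so shared ancestry counts as shared signal.  On a
star tree with equal branch lengths this reduces to classical Jaccard
dissimilarity on taxon sets.

Cells (or taxonomic groups, in the fuzzy-comparison layer) are then
agglomerated with unweighted average linkage; cutting the dendrogram
below the k-1 highest merges yields k phylogenetic regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from ._errors import InvalidParameterError, ValidationError
from .tree import BranchIncidence

__all__ = [
    "DissimilarityMatrix",
    "Dendrogram",
    "phylo_jaccard",
    "pairwise_phylo_jaccard",
    "average_linkage_cluster",
    "cut_clusters",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarity in [0, 1] with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("matrix shape does not match ids")
        self.values = v

    def validate(self):
        v = self.values
        if np.isnan(v).any():
            raise ValidationError("dissimilarity matrix contains NaN")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity diagonal is not zero")

    def loc(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DissimilarityMatrix":
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


@dataclass
class Dendrogram:
    """Average-linkage merge tree (scipy linkage encoding + leaf labels)."""

    merges: np.ndarray  # (n-1, 4) scipy linkage matrix
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def to_newick(self) -> str:
        n = self.n_leaves
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + k
            height[node] = h
            text[node] = (
                f"({text[a]}:{h - height[a]:.10g},{text[b]}:{h - height[b]:.10g})"
            )
        return text[n + len(self.merges) - 1] + ";"


def phylo_jaccard(incidence: BranchIncidence, cell_a, cell_b) -> float:
    """Phylo-jaccard dissimilarity between two materialized cells."""
    ia = incidence.cell_index(cell_a)
    ib = incidence.cell_index(cell_b)
    in_a = incidence.incidence[ia]
    in_b = incidence.incidence[ib]
    shared = float(incidence.lengths[in_a & in_b].sum())
    union = float(incidence.lengths[in_a | in_b].sum())
    if union == 0.0:
        return 0.0
    return 1.0 - shared / union


def pairwise_phylo_jaccard(incidence: BranchIncidence) -> DissimilarityMatrix:
    """Full symmetric matrix of phylo-jaccard scores between cells."""
    n = len(incidence.cells)
    if n < 2:
        raise InvalidParameterError("need at least 2 cells")
    W = incidence.incidence.astype(float) * incidence.lengths
    shared = incidence.incidence.astype(float) @ W.T
    totals = np.diag(shared).copy()
    union = totals[:, None] + totals[None, :] - shared
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(union > 0, 1.0 - shared / union, 0.0)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return DissimilarityMatrix(list(map(str, incidence.cells)), d)


def average_linkage_cluster(dissim: DissimilarityMatrix) -> Dendrogram:
    """Unweighted average-linkage (UPGMA-style) agglomeration.

    Items are sorted lexicographically first so that ties in merge
    distance resolve toward the smallest item ids, deterministically.
    """
    if len(dissim.ids) < 2:
        raise InvalidParameterError("need at least 2 items to cluster")
    dissim.validate()
    order = np.argsort(np.asarray(dissim.ids, dtype=object))
    labels = [dissim.ids[i] for i in order]
    sub = dissim.values[np.ix_(order, order)]
    Z = linkage(squareform(sub, checks=False), method="average")
    return Dendrogram(merges=Z, labels=labels)


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """The k clusters obtained by removing the k-1 highest merges.

    Labels are 1..k, assigned in order of each cluster's
    lexicographically smallest member, so they are stable across runs.
    """
    n = dendrogram.n_leaves
    if not (1 <= k <= n):
        raise InvalidParameterError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for row in range(n - k):
        a, b = int(dendrogram.merges[row, 0]), int(dendrogram.merges[row, 1])
        node = n + row
        parent[find(a)] = node
        parent[find(b)] = node
    roots: dict[int, list[str]] = {}
    leaf_root = {}
    for i, lab in enumerate(dendrogram.labels):
        r = find(i)
        roots.setdefault(r, []).append(lab)
        leaf_root[lab] = r
    ordered = sorted(roots.values(), key=lambda members: min(members))
    label_of = {}
    for num, members in enumerate(ordered, start=1):
        for m in members:
            label_of[m] = num
    return pd.Series(
        [label_of[lab] for lab in dendrogram.labels],
        index=dendrogram.labels,
        name="cluster",
    )
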