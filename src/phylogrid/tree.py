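"""Rooted trees and the branch-cell incidence structure.

All phylogenetic surfaces in this package (PD, PE, their relative
variants, and phylo-jaccard dissimilarity) are computed from the same
object: for every *counted* branch of a rooted tree, its length ``L_b``
and the set of grid cells in which at least one descendant tip occurs
(branch range ``R_b``).  "Counted" branches are every branch except the
stem above the root node, which is retained on the tree object but never
enters totals, equalization, or any metric.

Trees are handled through :mod:`dendropy`; this module adds the incidence
construction, the equal-branch-length comparison tree used by relative
PD/PE, and validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from ._errors import (
    DegenerateTreeError,
    FormatError,
    NameMismatchError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_tree",
    "write_tree",
    "tip_labels",
    "counted_nodes",
    "total_branch_length",
    "equalize_branch_lengths",
    "tree_arrays",
    "branch_incidence",
    "BranchIncidence",
]


def read_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted tree from a newick string or file path.

    Branch lengths absent from the source default to 0 (with a logged
    warning).  A stem length on the root, if present, is retained but is
    excluded from every metric.

    Raises
    ------
    FormatError
        If the newick text cannot be parsed.
    ValidationError
        If tip labels are duplicated or a length is negative/non-finite.
    """
    from dendropy.dataio.newickreader import NewickReader

    source = str(newick)
    try:
        if "(" in source or ";" in source:
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=source, schema="newick")
    except NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip labels: {exc}") from exc
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise FormatError(f"could not parse newick input: {exc}") from exc
    _validate_tree(tree)
    return tree


def write_tree(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s)
    return s


def _validate_tree(tree: dendropy.Tree) -> None:
    labels = tip_labels(tree)
    seen, dups = set(), set()
    for lab in labels:
        if lab in seen:
            dups.add(lab)
        seen.add(lab)
    if dups:
        raise ValidationError(f"duplicate tip labels: {sorted(dups)}")
    n_missing = 0
    for nd in tree.preorder_node_iter():
        if nd.edge.length is None:
            nd.edge.length = 0.0
            if nd is not tree.seed_node:
                n_missing += 1
        elif not np.isfinite(nd.edge.length) or nd.edge.length < 0:
            raise ValidationError(
                f"branch length {nd.edge.length!r} is negative or non-finite"
            )
    if n_missing:
        logger.warning("%d branch lengths missing; defaulted to 0", n_missing)


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def counted_nodes(tree: dendropy.Tree) -> list[dendropy.Node]:
    """Nodes subtending counted branches, in postorder (root stem excluded)."""
    return [nd for nd in tree.postorder_node_iter() if nd is not tree.seed_node]


def total_branch_length(tree: dendropy.Tree) -> float:
    return float(sum(nd.edge.length or 0.0 for nd in counted_nodes(tree)))


def equalize_branch_lengths(tree: dendropy.Tree) -> dendropy.Tree:
    """Comparison tree: same topology, every counted branch of equal length.

    Each counted branch is set to (total counted length) / (number of
    counted branches), so the total tree length is preserved.  The root
    stem, never counted, is left untouched.
    """
    nodes = counted_nodes(tree)
    total = float(sum(nd.edge.length or 0.0 for nd in nodes))
    if total <= 0.0:
        raise DegenerateTreeError("tree has zero total branch length")
    out = tree.clone(depth=1)
    mean = total / len(nodes)
    for nd in counted_nodes(out):
        nd.edge.length = mean
    return out


def tree_arrays(tree: dendropy.Tree, taxa: list[str]):
    """Vectorized view of the counted branches for a fixed taxon ordering.

    Returns ``(branch_ids, lengths, membership, is_internal)`` where
    ``membership`` is a boolean (n_taxa, n_branches) matrix marking, for
    each branch, which of the given taxa are descendant tips.  Taxa must
    be a subset of the tree's tips; tree tips absent from ``taxa``
    contribute empty membership (they simply never occur in any cell).
    """
    tips = set(tip_labels(tree))
    missing = [t for t in taxa if t not in tips]
    if missing:
        raise NameMismatchError(
            f"taxa absent from tree: {missing}", missing_from_tree=missing
        )
    col = {t: i for i, t in enumerate(taxa)}
    nodes = counted_nodes(tree)
    nb, nt = len(nodes), len(taxa)
    membership = np.zeros((nt, nb), dtype=bool)
    lengths = np.empty(nb, dtype=float)
    is_internal = np.zeros(nb, dtype=bool)
    branch_ids = []
    node_row = {}
    for j, nd in enumerate(nodes):
        lengths[j] = nd.edge.length or 0.0
        if nd.is_leaf():
            lab = nd.taxon.label
            branch_ids.append(f"tip:{lab}")
            if lab in col:
                membership[col[lab], j] = True
        else:
            is_internal[j] = True
            branch_ids.append(f"node:{j}")
            for ch in nd.child_nodes():
                membership[:, j] |= membership[:, node_row[id(ch)]]
        node_row[id(nd)] = j
    return branch_ids, lengths, membership, is_internal


@dataclass
class BranchIncidence:
    """Per-branch length, cell set, and range, over a fixed cell grid.

    ``incidence[c, b]`` is True when branch ``b`` is counted for cell
    ``c``.  Under the default tips-to-root convention a branch is counted
    wherever any of its descendant tips is present; under the crown
    convention, branches ancestral to *all* of a cell's taxa are dropped
    (except tip branches, so single-taxon cells keep their terminal
    branch).
    """

    cells: pd.Index
    branch_ids: list[str]
    lengths: np.ndarray
    incidence: np.ndarray  # bool, (n_cells, n_branches)
    ranges: np.ndarray  # int, per-branch cell counts R_b
    convention: str = "root"
    coords: pd.DataFrame | None = None
    taxa: list[str] = field(default_factory=list)
    membership: np.ndarray | None = None  # (n_taxa, n_branches), for reuse
    is_internal: np.ndarray | None = None

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())

    def cell_index(self, cell_id) -> int:
        loc = self.cells.get_indexer([cell_id])[0]
        if loc < 0:
            raise KeyError(f"unknown cell {cell_id!r}")
        return int(loc)

    def to_frame(self) -> pd.DataFrame:
        """Branch table: id, length, range and the occupied cell list."""
        cell_lists = [
            ";".join(map(str, self.cells[self.incidence[:, j]]))
            for j in range(len(self.branch_ids))
        ]
        return pd.DataFrame(
            {
                "branch_id": self.branch_ids,
                "length": self.lengths,
                "range": self.ranges,
                "cells": cell_lists,
            }
        )


def crown_incidence(
    X: np.ndarray, membership: np.ndarray, is_internal: np.ndarray
) -> np.ndarray:
    """Per-cell branch sets under the crown (spanning-subtree) convention."""
    counts = X.astype(np.float32) @ membership.astype(np.float32)
    richness = X.sum(axis=1).astype(np.float32)
    inc = counts > 0
    covers_all = counts == richness[:, None]
    inc &= ~(is_internal[None, :] & covers_all)
    return inc


def branch_incidence(tree, matrix, convention: str = "root") -> BranchIncidence:
    """Build the branch-cell incidence for an aligned tree and matrix.

    A single postorder pass unions tip presences upward; matrix taxa must
    be a subset of the tree's tips (tips absent from the matrix simply
    have empty cell sets).
    """
    if convention not in ("root", "crown"):
        raise ValueError(f"unknown convention {convention!r}")
    branch_ids, lengths, membership, is_internal = tree_arrays(
        tree, list(matrix.taxa)
    )
    X = matrix.values
    if convention == "root":
        inc = (X.astype(np.float32) @ membership.astype(np.float32)) > 0
    else:
        inc = crown_incidence(X, membership, is_internal)
    return BranchIncidence(
        cells=matrix.data.index,
        branch_ids=branch_ids,
        lengths=lengths,
        incidence=inc,
        ranges=inc.sum(axis=0),
        convention=convention,
        coords=matrix.cells,
        taxa=list(matrix.taxa),
        membership=membership,
        is_internal=is_internal,
    )
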