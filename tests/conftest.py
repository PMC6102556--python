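"""Shared fixtures: small worked datasets and an independent oracle.

The oracle recomputes every per-cell metric by explicit tip-to-root
path enumeration (sets of edges, summed lengths), with no shared code
path with the package's vectorized incidence machinery.
"""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
import pytest

from phylogrid import PresenceAbsenceMatrix

FOUR_TIP_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"
THREE_CELLS = {"c1": {"A", "B"}, "c2": {"C"}, "c3": {"A", "C", "D"}}


def build_matrix(cells: dict[str, set[str]], taxa=None,
                 coords=None) -> PresenceAbsenceMatrix:
    taxa = sorted(taxa or set().union(*cells.values()))
    ids = sorted(cells)
    data = pd.DataFrame(
        [[t in cells[c] for t in taxa] for c in ids], index=ids, columns=taxa
    )
    if coords is None:
        coords = pd.DataFrame(
            {"x": [25_000.0 * (i + 0.5) for i in range(len(ids))],
             "y": [12_500.0] * len(ids)},
            index=ids,
        )
    return PresenceAbsenceMatrix(data, coords)


class PathOracle:
    """Brute-force metrics via explicit tip-to-root path enumeration."""

    def __init__(self, newick: str, cells: dict[str, set[str]]):
        self.tree = dendropy.Tree.get(data=newick, schema="newick")
        self.cells = {c: set(s) for c, s in cells.items()}
        self.paths: dict[str, list] = {}
        for leaf in self.tree.leaf_node_iter():
            path, nd = [], leaf
            while nd.parent_node is not None:
                path.append(nd)  # a node stands for its subtending edge
                nd = nd.parent_node
            self.paths[leaf.taxon.label] = path
        self.edges = [
            nd for nd in self.tree.postorder_node_iter()
            if nd is not self.tree.seed_node
        ]
        total = sum(e.edge.length or 0.0 for e in self.edges)
        self.eq_length = total / len(self.edges)
        self.total_length = total

    def _cell_edges(self, c) -> set[int]:
        out = set()
        for t in self.cells[c]:
            out.update(id(e) for e in self.paths[t])
        return out

    def _edge_len(self, e) -> float:
        return e.edge.length or 0.0

    def tr(self, c) -> float:
        return float(len(self.cells[c]))

    def _range(self, taxon) -> int:
        return sum(taxon in s for s in self.cells.values())

    def we(self, c) -> float:
        return sum(1.0 / self._range(t) for t in self.cells[c])

    def _edge_range(self, e) -> int:
        return sum(id(e) in self._cell_edges(c) for c in self.cells)

    def pd(self, c, equalized=False) -> float:
        ids = self._cell_edges(c)
        return sum(
            (self.eq_length if equalized else self._edge_len(e))
            for e in self.edges if id(e) in ids
        )

    def pe(self, c, equalized=False) -> float:
        ids = self._cell_edges(c)
        return sum(
            (self.eq_length if equalized else self._edge_len(e))
            / self._edge_range(e)
            for e in self.edges
            if id(e) in ids and self._edge_range(e) > 0
        )

    def rpd(self, c) -> float:
        return self.pd(c) / self.pd(c, equalized=True)

    def jaccard(self, a, b) -> float:
        ea, eb = self._cell_edges(a), self._cell_edges(b)
        shared = sum(self._edge_len(e) for e in self.edges if id(e) in ea & eb)
        union = sum(self._edge_len(e) for e in self.edges if id(e) in ea | eb)
        return 0.0 if union == 0 else 1.0 - shared / union


def enumerate_rooted_topologies(labels: tuple[str, ...]):
    """All rooted binary labeled topologies as nested tuples."""
    if len(labels) == 1:
        yield labels[0]
        return
    rest = labels[1:]
    for mask in range(2 ** len(rest)):
        left = [labels[0]] + [t for i, t in enumerate(rest) if mask >> i & 1]
        right = [t for i, t in enumerate(rest) if not mask >> i & 1]
        if not right:
            continue
        for lt in enumerate_rooted_topologies(tuple(left)):
            for rt in enumerate_rooted_topologies(tuple(right)):
                yield (lt, rt)


def topology_to_newick(topo, lengths: dict | None, rng=None) -> str:
    """Nested-tuple topology to newick, with drawn branch lengths."""

    def render(node):
        if isinstance(node, str):
            ln = rng.uniform(0.1, 2.0) if rng is not None else 1.0
            return f"{node}:{ln:.6f}"
        parts = ",".join(render(ch) for ch in node)
        ln = rng.uniform(0.1, 2.0) if rng is not None else 1.0
        return f"({parts}):{ln:.6f}"

    if isinstance(topo, str):
        return f"({topo}:1);"
    return ",".join(render(ch) for ch in topo).join("()") + ";"


@pytest.fixture
def four_tip_tree_newick():
    return FOUR_TIP_NEWICK


@pytest.fixture
def three_cell_matrix():
    return build_matrix(THREE_CELLS)


@pytest.fixture
def oracle():
    return PathOracle


@pytest.fixture
def rng():
    return np.random.default_rng(20150)
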