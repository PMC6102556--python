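"""Synthetic trees, ranges, and endemism scenarios.

The analysis pipeline is exercised end-to-end on generated data with
the statistical structure the method assumes: trees with heterogeneous
branch lengths, spatially clustered species ranges on an equal-area
grid of 25 km cells, multiple co-registered taxonomic groups, and
optional injected concentrations of rare short-branch (neo) or rare
long-branch (paleo) taxa.  These generators are stand-ins for real
herbarium/audit occurrence data and published phylogenies: they supply
the *structure* the metrics consume, not ecological realism (see
docs/methods.md for what they do and do not emulate).

All generators are deterministic functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._errors import (
    InfeasibleMarginsError,
    InvalidParameterError,
    InvalidScenarioError,
)
from .grid import PresenceAbsenceMatrix
from .randomize import _burn_in, curveball
from .tree import counted_nodes

__all__ = [
    "RangeModel",
    "EndemismScenario",
    "simulate_tree",
    "simulate_occurrences",
    "inject_endemism_scenario",
    "simulate_null_dataset",
]


@dataclass
class RangeModel:
    """Disc-shaped species ranges with lognormal radii, in cell units.

    Defaults describe a 20 x 10 grid of 25 km cells (a 500 x 250 km
    study region) and range radii with median 2.5 cells (~62 km) and
    log-sd 0.6 — typical of continental-scale species occurrence
    compilations.  ``center_clustering`` > 0 draws range centers from a
    Gaussian mixture instead of uniformly, producing the spatially
    autocorrelated composition the beta-diversity stage assumes.
    """

    n_cells_x: int = 20
    n_cells_y: int = 10
    range_radius_log_mean: float = float(np.log(2.5))
    range_radius_log_sd: float = 0.6
    center_clustering: float = 0.0

    def __post_init__(self):
        if self.n_cells_x < 1 or self.n_cells_y < 1:
            raise InvalidParameterError("grid dimensions must be >= 1")
        if self.range_radius_log_sd < 0:
            raise InvalidParameterError("lognormal sd must be >= 0")
        if self.center_clustering < 0:
            raise InvalidParameterError("center_clustering must be >= 0")


@dataclass
class EndemismScenario:
    """Injected concentration of rare neo (short) or paleo (long) branches."""

    kind: str  # "neo" or "paleo"
    target_cells: frozenset
    n_taxa: int = 1
    branch_scale: float = 10.0
    range_cells: int = 1

    def __post_init__(self):
        if self.kind not in ("neo", "paleo"):
            raise InvalidParameterError("kind must be 'neo' or 'paleo'")
        if self.n_taxa < 1:
            raise InvalidParameterError("n_taxa must be >= 1")
        if self.branch_scale <= 0:
            raise InvalidParameterError("branch_scale must be > 0")
        if self.range_cells < max(1, len(self.target_cells)):
            raise InvalidParameterError(
                "range_cells must cover the target cells"
            )
        self.target_cells = frozenset(self.target_cells)


def simulate_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with exponential waiting times.

    The initial lineage before the first split becomes the root stem
    (never counted by metrics); the tree is ultrametric with exactly
    ``n_taxa`` uniquely labeled tips and all counted branch lengths > 0.
    """
    if n_taxa < 1:
        raise InvalidParameterError("n_taxa must be >= 1")
    if birth_rate <= 0:
        raise InvalidParameterError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    t = 0.0
    active: list[tuple[dendropy.Node, float]] = [(tree.seed_node, 0.0)]
    if n_taxa == 1:
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        tree.seed_node.edge.length = 0.0
        active = [(child, 0.0)]
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node, birth = active.pop(int(rng.integers(k)))
        node.edge.length = t - birth
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        active.append((left, t))
        active.append((right, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_taxa))
    width = len(str(n_taxa))
    for i, (node, birth) in enumerate(active):
        node.edge.length = t_end - birth
        node.taxon = tree.taxon_namespace.require_taxon(
            label=f"t{i + 1:0{width}d}"
        )
    return tree


def _range_centers(n: int, model: RangeModel, rng) -> np.ndarray:
    nx, ny = model.n_cells_x, model.n_cells_y
    if model.center_clustering == 0:
        return rng.uniform([0, 0], [nx, ny], size=(n, 2))
    n_comp = 4
    comp = rng.uniform([0, 0], [nx, ny], size=(n_comp, 2))
    sd = (min(nx, ny) / 4.0) / (1.0 + model.center_clustering)
    which = rng.integers(n_comp, size=n)
    return comp[which] + rng.normal(0.0, sd, size=(n, 2))


def simulate_occurrences(
    tree: dendropy.Tree,
    model: RangeModel,
    seed: int = 0,
    cell_size: float = 25_000.0,
) -> PresenceAbsenceMatrix:
    """Disc ranges on the grid: one drawn center and radius per tip.

    A taxon occupies every cell whose center lies within its disc,
    clipped to the grid; the cell containing the (clipped) range center
    is always occupied, so each tip has range >= 1.
    """
    taxa = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    if not taxa:
        raise InvalidParameterError("tree has no tips")
    rng = np.random.default_rng(seed)
    nx, ny = model.n_cells_x, model.n_cells_y
    centers = _range_centers(len(taxa), model, rng)
    radii = rng.lognormal(
        model.range_radius_log_mean, model.range_radius_log_sd, size=len(taxa)
    )
    gx, gy = np.meshgrid(
        np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij"
    )
    X = np.zeros((nx * ny, len(taxa)), dtype=bool)
    for i, ((cx, cy), r) in enumerate(zip(centers, radii)):
        disc = (gx - cx) ** 2 + (gy - cy) ** 2 <= r**2
        col = disc.reshape(-1)
        hx = int(np.clip(np.floor(cx), 0, nx - 1))
        hy = int(np.clip(np.floor(cy), 0, ny - 1))
        col[hx * ny + hy] = True
        X[:, i] = col
    ids = [f"{i}_{j}" for i in range(nx) for j in range(ny)]
    coords = pd.DataFrame(
        {
            "x": (gx.reshape(-1)) * cell_size,
            "y": (gy.reshape(-1)) * cell_size,
        },
        index=ids,
    )
    data = pd.DataFrame(X, index=ids, columns=taxa)
    keep = data.any(axis=1)
    return PresenceAbsenceMatrix(data.loc[keep], coords.loc[keep])


def inject_endemism_scenario(
    tree: dendropy.Tree,
    matrix: PresenceAbsenceMatrix,
    scenario: EndemismScenario,
    seed: int = 0,
):
    """Graft rare-endemic tips onto a tree and place them near a target.

    New tips are attached as sisters at a random point on a random
    counted branch; each tip's subtending branch is an independent draw
    from the upper half (median..max) of the existing tip-length
    distribution, multiplied by ``branch_scale`` (< 1 shrinks for neo
    scenarios, > 1 stretches for paleo).  Each new taxon occupies
    exactly ``range_cells`` cells: the target cells plus their nearest
    neighbors.  The base tree and matrix are left untouched.
    """
    missing = [c for c in scenario.target_cells if c not in matrix.cell_ids]
    if missing:
        raise InvalidScenarioError(f"target cells absent from grid: {missing}")
    rng = np.random.default_rng(seed)
    t2 = tree.clone(depth=1)
    tip_lengths = np.array(
        [lf.edge.length or 0.0 for lf in t2.leaf_node_iter()], dtype=float
    )
    lo, hi = float(np.median(tip_lengths)), float(tip_lengths.max())
    draws = rng.uniform(lo, hi if hi > lo else lo + 1e-12, scenario.n_taxa)
    new_lengths = draws * scenario.branch_scale

    nodes = counted_nodes(t2)
    host = nodes[int(rng.integers(len(nodes)))]
    frac = float(rng.uniform(0.1, 0.9))
    parent = host.parent_node
    attach = dendropy.Node()
    orig_len = host.edge.length or 0.0
    parent.remove_child(host)
    parent.add_child(attach)
    attach.edge.length = frac * orig_len
    attach.add_child(host)
    host.edge.length = (1.0 - frac) * orig_len

    existing = {lf.taxon.label for lf in t2.leaf_node_iter()}
    names = []
    for i in range(scenario.n_taxa):
        name = f"{scenario.kind}_{i + 1}"
        while name in existing:
            name += "x"
        existing.add(name)
        names.append(name)
        tip = dendropy.Node()
        tip.taxon = t2.taxon_namespace.require_taxon(label=name)
        tip.edge.length = float(new_lengths[i])
        attach.add_child(tip)

    # range: target cells plus nearest cells by centroid distance
    targets = sorted(scenario.target_cells)
    if matrix.cells is not None:
        center = matrix.cells.loc[targets].mean(axis=0)
        dist = np.hypot(
            matrix.cells["x"] - center["x"], matrix.cells["y"] - center["y"]
        ).sort_values(kind="stable")
        pool = [c for c in dist.index if c not in scenario.target_cells]
    else:
        pool = [c for c in matrix.cell_ids if c not in scenario.target_cells]
    chosen = targets + pool[: scenario.range_cells - len(targets)]
    data = matrix.data.copy()
    for name in names:
        col = pd.Series(False, index=data.index)
        col.loc[chosen] = True
        data[name] = col
    data = data.sort_index(axis=1)
    return t2, PresenceAbsenceMatrix(data, matrix.cells)


def _gale_ryser_feasible(row_sums: np.ndarray, col_sums: np.ndarray) -> bool:
    d = np.sort(col_sums)[::-1]
    prefix = np.cumsum(d)
    for k in range(1, len(d) + 1):
        if prefix[k - 1] > np.minimum(row_sums, k).sum():
            return False
    return True


def simulate_null_dataset(
    richness: dict, ranges: dict, seed: int = 0,
    burn_in_swaps_factor: float = 1.0,
) -> PresenceAbsenceMatrix:
    """A uniform-margin draw: richness and range sizes held constant.

    Feasibility is checked (sum equality and the Gale-Ryser condition);
    a greedy realization is then randomized with the same curveball
    sampler the null-model module uses.
    """
    cells = list(richness)
    taxa = list(ranges)
    r = np.array([richness[c] for c in cells], dtype=int)
    d = np.array([ranges[t] for t in taxa], dtype=int)
    if (r < 0).any() or (d < 1).any():
        raise InvalidParameterError("richness must be >= 0, ranges >= 1")
    if r.sum() != d.sum():
        raise InfeasibleMarginsError(
            f"sum of richness ({r.sum()}) != sum of ranges ({d.sum()})"
        )
    if (d > len(cells)).any() or (r > len(taxa)).any():
        raise InfeasibleMarginsError("a margin exceeds the grid/taxon count")
    if not _gale_ryser_feasible(r, d):
        raise InfeasibleMarginsError("margins fail the Gale-Ryser condition")
    X = np.zeros((len(cells), len(taxa)), dtype=bool)
    residual = r.astype(int).copy()
    for j in np.argsort(-d, kind="stable"):
        pick = np.argsort(-residual, kind="stable")[: d[j]]
        if residual[pick].min() < 1:
            raise InfeasibleMarginsError("margins admit no binary matrix")
        X[pick, j] = True
        residual[pick] -= 1
    curveball(X, _burn_in(int(X.sum()), burn_in_swaps_factor), seed)
    return PresenceAbsenceMatrix(pd.DataFrame(X, index=cells, columns=taxa))
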