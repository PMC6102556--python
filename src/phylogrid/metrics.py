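"""Per-cell diversity and endemism surfaces.

Six observed metrics per grid cell:

- **TR** taxon richness, the number of taxa present;
- **WE** weighted endemism, ``sum_i 1/r_i`` over the cell's taxa, where
  ``r_i`` is taxon i's range in cells (Crisp-style inverse-range
  weighting);
- **PD** phylogenetic diversity, the summed length of the branches on
  the union of tip-to-root paths of the cell's taxa (Faith);
- **PE** phylogenetic endemism, PD with each branch length divided by
  its range ``R_b`` (Rosauer);
- **RPD/RPE** relative PD/PE, the observed value divided by the same
  quantity on a comparison tree whose branches are all of equal length;
  values above 1 flag concentrations of unusually long branches, below 1
  unusually short ones.

Two conservation identities pin the endemism metrics down: summed over
all cells, WE equals the number of taxa, and PE equals the total counted
tree length (each branch contributes ``L_b/R_b`` in exactly ``R_b``
cells).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import InvalidParameterError, UndefinedCellError
from .tree import BranchIncidence

__all__ = [
    "DiversitySurface",
    "taxon_richness",
    "weighted_endemism",
    "phylogenetic_diversity",
    "phylogenetic_endemism",
    "relative_metric",
]

METRICS = ("TR", "WE", "PD", "PE", "RPD", "RPE")


@dataclass
class DiversitySurface:
    """A labeled map cell -> value for one metric of one group.

    Only materialized (nonempty) cells carry values; absence is encoded
    as a missing cell, never as 0.
    """

    metric: str
    values: pd.Series
    group: str | None = None
    coords: pd.DataFrame | None = None

    def __post_init__(self):
        self.values = self.values.astype(float)
        self.values.name = self.metric
        if self.coords is not None:
            self.coords = self.coords.loc[self.values.index]

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"value": self.values})
        if self.coords is not None:
            df.insert(0, "y", self.coords["y"])
            df.insert(0, "x", self.coords["x"])
        df.insert(0, "metric", self.metric)
        df.insert(1, "group", self.group or "")
        df.index.name = "cell_id"
        return df


def _require_nonempty(matrix):
    if matrix.data.shape[0] == 0 or matrix.data.shape[1] == 0:
        raise InvalidParameterError("matrix has no cells or no taxa")


def taxon_richness(matrix, group: str | None = None) -> DiversitySurface:
    """TR(c): number of taxa present in cell c (row sums)."""
    _require_nonempty(matrix)
    return DiversitySurface("TR", matrix.richness.astype(float), group,
                            matrix.cells)


def weighted_endemism(matrix, group: str | None = None) -> DiversitySurface:
    """WE(c) = sum over taxa present in c of 1/r_i."""
    _require_nonempty(matrix)
    inv_range = 1.0 / matrix.ranges.to_numpy(dtype=float)
    we = matrix.values @ inv_range
    return DiversitySurface(
        "WE", pd.Series(we, index=matrix.cell_ids), group, matrix.cells
    )


def phylogenetic_diversity(
    incidence: BranchIncidence, group: str | None = None
) -> DiversitySurface:
    """PD(c) = sum of L_b over branches counted for cell c."""
    pd_vals = incidence.incidence @ incidence.lengths
    return DiversitySurface(
        "PD", pd.Series(pd_vals, index=incidence.cells), group, incidence.coords
    )


def phylogenetic_endemism(
    incidence: BranchIncidence, group: str | None = None
) -> DiversitySurface:
    """PE(c) = sum of L_b / R_b over branches counted for cell c."""
    R = incidence.ranges
    w = np.divide(
        incidence.lengths, R, out=np.zeros_like(incidence.lengths),
        where=R > 0,
    )
    pe_vals = incidence.incidence @ w
    return DiversitySurface(
        "PE", pd.Series(pe_vals, index=incidence.cells), group, incidence.coords
    )


_RELATIVE_NAMES = {"PD": "RPD", "PE": "RPE"}


def relative_metric(
    observed: DiversitySurface, comparison: DiversitySurface
) -> DiversitySurface:
    """Cell-wise ratio observed/comparison (RPD, RPE).

    The comparison surface is the same metric computed on the
    equal-branch-length tree; topology and presences are unchanged by
    equalization, so both surfaces live on identical cell sets and the
    branch ranges in the comparison PE are the same ``R_b``.
    """
    if not observed.cells.equals(comparison.cells):
        raise InvalidParameterError(
            "observed and comparison surfaces cover different cell sets"
        )
    zero = comparison.values[comparison.values == 0.0]
    if len(zero):
        raise UndefinedCellError(
            f"comparison value 0 in {len(zero)} cells", cells=list(zero.index)
        )
    name = _RELATIVE_NAMES.get(
        observed.metric, f"{observed.metric}/{comparison.metric}"
    )
    return DiversitySurface(
        name, observed.values / comparison.values, observed.group,
        observed.coords,
    )
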