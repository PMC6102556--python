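"""Occurrence tables and aggregation onto an equal-area grid.

Point records (taxon, x, y) are assumed to be in a planar equal-area
projection in meters; no reprojection is performed.  Records are binned
into square cells of side ``cell_size`` (default 25 km) using half-open
intervals ``[low, high)`` and floor division, which makes boundary
assignment bit-reproducible: a point exactly on a cell edge belongs to
the higher cell.

The product is a :class:`PresenceAbsenceMatrix`: binary cell x taxon
incidence with per-cell richness (row sums) and per-taxon range ``r_i``
(column sums, in cells) — the quantity weighted endemism and the
fixed-margin null model both hold constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import (
    EmptyIntersectionError,
    FormatError,
    InvalidParameterError,
    NameMismatchError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "OccurrenceTable",
    "GridSpec",
    "PresenceAbsenceMatrix",
    "read_occurrences",
    "aggregate_to_grid",
    "align_matrix_to_tree",
]


@dataclass
class OccurrenceTable:
    """Point records; one row per (taxon, x, y), coordinates in meters."""

    records: pd.DataFrame  # columns: taxon, x, y
    n_dropped: int = 0

    def __post_init__(self):
        required = {"taxon", "x", "y"}
        if not required.issubset(self.records.columns):
            raise FormatError(
                f"occurrence table needs columns {sorted(required)}"
            )

    def __len__(self):
        return len(self.records)


@dataclass
class GridSpec:
    """Square-cell grid: cell size and origin in meters, optional mask.

    The origin defaults to the floor of the data's minimum x/y to the
    nearest ``cell_size`` multiple.  ``mask`` is an optional shapely
    polygon; points on its boundary are kept (boundary-inclusive).
    """

    cell_size: float = 25_000.0
    origin_x: float | None = None
    origin_y: float | None = None
    mask: object | None = None

    def __post_init__(self):
        if self.cell_size <= 0:
            raise InvalidParameterError("cell_size must be > 0")


def read_occurrences(path, columns=None, delimiter=",") -> OccurrenceTable:
    """Read a delimited occurrence table, mapping columns to taxon/x/y.

    ``columns`` maps the roles ``taxon``/``x``/``y`` to column names in
    the file (default: identical names).  Rows with empty taxon names or
    unparseable coordinates are dropped and counted in ``n_dropped``.
    """
    columns = columns or {"taxon": "taxon", "x": "x", "y": "y"}
    try:
        raw = pd.read_csv(path, delimiter=delimiter)
    except Exception as exc:
        raise FormatError(f"could not read occurrence table {path}: {exc}") from exc
    missing = [v for v in columns.values() if v not in raw.columns]
    if missing:
        raise FormatError(f"mapped columns absent from {path}: {missing}")
    df = pd.DataFrame(
        {
            "taxon": raw[columns["taxon"]].astype("string"),
            "x": pd.to_numeric(raw[columns["x"]], errors="coerce"),
            "y": pd.to_numeric(raw[columns["y"]], errors="coerce"),
        }
    )
    ok = (
        df["taxon"].notna()
        & (df["taxon"].str.strip() != "")
        & np.isfinite(df["x"].to_numpy(dtype=float, na_value=np.nan))
        & np.isfinite(df["y"].to_numpy(dtype=float, na_value=np.nan))
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d unusable occurrence rows", n_dropped)
    out = df[ok].reset_index(drop=True)
    out["taxon"] = out["taxon"].astype(str)
    return OccurrenceTable(records=out, n_dropped=n_dropped)


@dataclass
class PresenceAbsenceMatrix:
    """Binary cell x taxon incidence over materialized (nonempty) cells.

    ``data`` is a boolean DataFrame indexed by cell id with taxon
    columns; ``cells`` holds centroid coordinates (x, y) per cell id.
    Every retained cell has richness >= 1 and every retained taxon has
    range >= 1.
    """

    data: pd.DataFrame
    cells: pd.DataFrame | None = None

    def __post_init__(self):
        self.data = self.data.astype(bool)
        if self.cells is not None:
            self.cells = self.cells.loc[self.data.index]

    # -- derived quantities -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=bool)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.columns)

    @property
    def cell_ids(self) -> pd.Index:
        return self.data.index

    @property
    def richness(self) -> pd.Series:
        return self.data.sum(axis=1)

    @property
    def ranges(self) -> pd.Series:
        return self.data.sum(axis=0)

    @property
    def n_presences(self) -> int:
        return int(self.values.sum())

    def drop_empty(self) -> "PresenceAbsenceMatrix":
        d = self.data.loc[self.data.any(axis=1), self.data.columns[self.data.any(axis=0)]]
        cells = self.cells.loc[d.index] if self.cells is not None else None
        return PresenceAbsenceMatrix(d, cells)

    def with_data(self, values: np.ndarray) -> "PresenceAbsenceMatrix":
        d = pd.DataFrame(values.astype(bool), index=self.data.index,
                         columns=self.data.columns)
        return PresenceAbsenceMatrix(d, self.cells)

    # -- I/O ----------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        long = self.data.stack()
        long = long[long].reset_index()
        long.columns = ["cell_id", "taxon", "presence"]
        long["presence"] = 1
        return long

    def to_wide_csv(self, path):
        wide = self.data.astype(int)
        if self.cells is not None:
            wide = pd.concat([self.cells, wide], axis=1)
        wide.to_csv(path, index_label="cell_id")

    def to_long_csv(self, path):
        self.to_long().to_csv(path, index=False)

    @classmethod
    def from_wide_csv(cls, path) -> "PresenceAbsenceMatrix":
        wide = pd.read_csv(path, index_col="cell_id")
        wide.index = wide.index.astype(str)
        coords = None
        if {"x", "y"}.issubset(wide.columns):
            coords = wide[["x", "y"]]
            wide = wide.drop(columns=["x", "y"])
        return cls(wide.astype(bool), coords)


def aggregate_to_grid(occ: OccurrenceTable, grid: GridSpec) -> PresenceAbsenceMatrix:
    """Bin records into grid cells and collapse duplicates to presences.

    Cell ids are ``"{ix}_{iy}"`` with ``ix = floor((x - origin_x)/cell_size)``;
    cells with no records are not materialized.
    """
    df = occ.records
    if len(df) == 0:
        empty = pd.DataFrame(dtype=bool)
        return PresenceAbsenceMatrix(empty, pd.DataFrame(columns=["x", "y"]))
    if grid.mask is not None:
        import shapely

        pts = shapely.points(df["x"].to_numpy(), df["y"].to_numpy())
        keep = shapely.covers(grid.mask, pts)
        df = df[keep]
        if len(df) == 0:
            empty = pd.DataFrame(dtype=bool)
            return PresenceAbsenceMatrix(empty, pd.DataFrame(columns=["x", "y"]))
    cs = grid.cell_size
    ox = grid.origin_x
    oy = grid.origin_y
    if ox is None:
        ox = np.floor(df["x"].min() / cs) * cs
    if oy is None:
        oy = np.floor(df["y"].min() / cs) * cs
    ix = np.floor((df["x"].to_numpy() - ox) / cs).astype(np.int64)
    iy = np.floor((df["y"].to_numpy() - oy) / cs).astype(np.int64)
    binned = pd.DataFrame(
        {"cell_id": [f"{i}_{j}" for i, j in zip(ix, iy)],
         "taxon": df["taxon"].to_numpy(), "ix": ix, "iy": iy}
    )
    data = (
        pd.crosstab(binned["cell_id"], binned["taxon"]) > 0
    )
    cent = binned.drop_duplicates("cell_id").set_index("cell_id")
    coords = pd.DataFrame(
        {
            "x": ox + (cent["ix"] + 0.5) * cs,
            "y": oy + (cent["iy"] + 0.5) * cs,
        }
    ).loc[data.index]
    data = data.sort_index().sort_index(axis=1)
    return PresenceAbsenceMatrix(data, coords.loc[data.index])


def align_matrix_to_tree(matrix, tree, policy: str = "prune-both"):
    """Reconcile matrix taxa and tree tips.

    ``strict`` errors on any mismatch; ``prune-both`` intersects the name
    sets, prunes the tree to the shared tips, drops now-empty cells, and
    returns the reduced pair.
    """
    from .tree import tip_labels

    mat_taxa = set(matrix.taxa)
    tips = set(tip_labels(tree))
    if not mat_taxa or not tips:
        raise InvalidParameterError("matrix and tree must be nonempty")
    shared = mat_taxa & tips
    if policy == "strict":
        if mat_taxa != tips:
            raise NameMismatchError(
                "matrix/tree name sets differ under strict policy: "
                f"matrix-only={sorted(mat_taxa - tips)}, "
                f"tree-only={sorted(tips - mat_taxa)}",
                missing_from_tree=mat_taxa - tips,
                missing_from_matrix=tips - mat_taxa,
            )
        return matrix, tree
    if policy != "prune-both":
        raise InvalidParameterError(f"unknown policy {policy!r}")
    if not shared:
        raise EmptyIntersectionError(
            "no taxa shared between matrix and tree",
            missing_from_tree=mat_taxa,
            missing_from_matrix=tips,
        )
    kept = sorted(shared)
    sub = matrix.data[kept]
    sub = sub.loc[sub.any(axis=1)]
    cells = matrix.cells.loc[sub.index] if matrix.cells is not None else None
    pruned_matrix = PresenceAbsenceMatrix(sub, cells)
    if tips == shared:
        pruned_tree = tree
    else:
        pruned_tree = tree.extract_tree_with_taxa_labels(labels=kept)
    return pruned_matrix, pruned_tree
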