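"""Cross-taxon concordance: standardization and summary surfaces.

Different taxonomic groups live on different scales (a fish fauna's PD
is not commensurate with a continental plant genus tree's), so each
group's surface is first min-max standardized to [0, 1].  Two summary
surfaces then compare groups:

- **mean-all**: per cell, the mean of the standardized values of the
  groups materialized there (groups without records in a cell are
  excluded from that cell's mean rather than imputed as zero, which
  would conflate "unsampled" with "no diversity");
- **mean-concordant**: restricted to cells where *every* group has a
  nonzero standardized value, the mean over all groups.

A leave-one-group-out variant quantifies how much a spatially
restricted group (e.g. an aquatic one) limits the concordant cell set;
dropping a group can only grow the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import InvalidParameterError, ValidationError
from .metrics import DiversitySurface

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordanceSummary",
    "minmax_standardize",
    "standardize_surfaces",
    "mean_all_cells",
    "mean_concordant_cells",
    "leave_group_out",
]


def minmax_standardize(
    surface: DiversitySurface, pooled_range: tuple[float, float] | None = None
) -> DiversitySurface:
    """Affine map of a surface onto [0, 1] via its own min/max.

    ``pooled_range`` substitutes a (min, max) pooled across groups for
    the group's own extrema.  A constant surface maps to all zeros with
    a logged warning.
    """
    v = surface.values
    if len(v) == 0:
        raise InvalidParameterError("cannot standardize an empty surface")
    lo, hi = (float(v.min()), float(v.max())) if pooled_range is None else pooled_range
    if hi == lo:
        logger.warning(
            "constant %s surface for group %s; standardized to 0",
            surface.metric, surface.group,
        )
        out = pd.Series(0.0, index=v.index)
    else:
        out = (v - lo) / (hi - lo)
    return DiversitySurface(surface.metric, out, surface.group, surface.coords)


def standardize_surfaces(
    surfaces: list[DiversitySurface], mode: str = "per-group"
) -> list[DiversitySurface]:
    """Standardize a set of same-metric group surfaces together.

    ``per-group`` uses each group's own min/max; ``pooled`` uses the
    min/max over all groups' values jointly.
    """
    if mode == "per-group":
        return [minmax_standardize(s) for s in surfaces]
    if mode == "pooled":
        allv = np.concatenate([s.values.to_numpy() for s in surfaces])
        rng = (float(allv.min()), float(allv.max()))
        return [minmax_standardize(s, pooled_range=rng) for s in surfaces]
    raise InvalidParameterError(f"unknown standardization mode {mode!r}")


def _check_groups(surfaces):
    if len(surfaces) < 2:
        raise InvalidParameterError("need at least 2 groups")
    metrics = {s.metric for s in surfaces}
    if len(metrics) > 1:
        raise ValidationError(f"mixed metrics: {sorted(metrics)}")


def _stack(surfaces) -> pd.DataFrame:
    return pd.concat(
        {s.group or f"g{i}": s.values for i, s in enumerate(surfaces)}, axis=1
    )


def _coords_union(surfaces) -> pd.DataFrame | None:
    frames = [s.coords for s in surfaces if s.coords is not None]
    if not frames:
        return None
    merged = pd.concat(frames)
    return merged[~merged.index.duplicated()]


def mean_all_cells(surfaces: list[DiversitySurface]) -> DiversitySurface:
    """Mean standardized value over the groups materialized per cell."""
    _check_groups(surfaces)
    table = _stack(surfaces)
    mean = table.mean(axis=1, skipna=True).sort_index()
    coords = _coords_union(surfaces)
    if coords is not None:
        coords = coords.loc[mean.index]
    return DiversitySurface(surfaces[0].metric, mean, "mean-all", coords)


@dataclass
class ConcordanceSummary:
    """Mean-all and mean-concordant surfaces for one metric."""

    metric: str
    groups: list[str]
    mean_all: DiversitySurface
    mean_concordant: DiversitySurface
    n_concordant: int
    concordant_change: int | None = None
    warnings: list[str] = field(default_factory=list)


def mean_concordant_cells(
    surfaces: list[DiversitySurface],
) -> ConcordanceSummary:
    """Summaries over all cells and over the concordant cell set.

    Concordant cells are those where every group is materialized with a
    nonzero standardized value.  An empty concordant set yields an
    empty summary with a warning, not an error.
    """
    _check_groups(surfaces)
    table = _stack(surfaces)
    concordant = table.index[(table.notna() & (table > 0)).all(axis=1)].sort_values()
    warnings = []
    if len(concordant) == 0:
        msg = "no concordant cells across groups " + str(list(table.columns))
        logger.warning(msg)
        warnings.append(msg)
    mc = table.loc[concordant].mean(axis=1)
    coords = _coords_union(surfaces)
    mc_coords = coords.loc[concordant] if coords is not None else None
    return ConcordanceSummary(
        metric=surfaces[0].metric,
        groups=[s.group or "" for s in surfaces],
        mean_all=mean_all_cells(surfaces),
        mean_concordant=DiversitySurface(
            surfaces[0].metric, mc, "mean-concordant", mc_coords
        ),
        n_concordant=int(len(concordant)),
        warnings=warnings,
    )


def leave_group_out(
    surfaces: list[DiversitySurface], group: str
) -> ConcordanceSummary:
    """Recompute both summaries without one group.

    Reports the change in concordant cell count relative to the full
    set of groups (never negative: intersecting fewer sets cannot
    shrink the intersection).
    """
    names = [s.group for s in surfaces]
    if group not in names:
        raise InvalidParameterError(f"group {group!r} not among {names}")
    kept = [s for s in surfaces if s.group != group]
    if len(kept) < 2:
        raise InvalidParameterError("fewer than 2 groups would remain")
    before = mean_concordant_cells(surfaces).n_concordant
    summary = mean_concordant_cells(kept)
    summary.concordant_change = summary.n_concordant - before
    return summary
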