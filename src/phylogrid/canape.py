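"""Rank-based significance tests and CANAPE endemism categories.

For each cell, the observed PD, RPD, PE (on the actual and on the
equal-branch-length comparison tree) and the RPE ratio are ranked
against ``n_reps`` (default 999) values recomputed on fixed-margin
randomizations of the presence-absence matrix.  Branch lengths stay
fixed; only the cell sets (and hence branch ranges) change per trial.

P-values use the permutation convention ``(1 + count) / (1 + n_reps)``
with ties counted toward significance in both tails, so p is never 0
and the test is conservative under ties.

CANAPE (categorical analysis of neo- and paleo-endemism) is a two-step
test.  Step one screens for significantly *high* PE (one-tailed,
alpha = 0.05); by default PE on the actual tree is used, optionally the
test passes if PE on either the actual or the comparison tree is
significant.  For cells passing step one, step two examines the RPE
ratio two-tailed: significantly high -> paleo-endemism (rare
long-branch lineages), significantly low -> neo-endemism (rare
short-branch lineages), otherwise mixed-endemism, upgraded to
super-endemism when the step-one p-value is at or below the stricter
alpha = 0.01.  Cells failing step one are not significant.  The five
categories are mutually exclusive and exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import AlignmentError, UnknownMetricError
from .randomize import RandomizationConfig, _burn_in, curveball
from .tree import counted_nodes, tree_arrays

__all__ = [
    "NullEnsemble",
    "SignificanceSurface",
    "CanapeMap",
    "build_null_ensemble",
    "significance_ranks",
    "canape_classify",
    "CATEGORIES",
]

ENSEMBLE_METRICS = ("TR", "PD", "RPD", "PE_actual", "PE_equalized", "RPE")
CATEGORIES = ("not-significant", "neo", "paleo", "mixed", "super")


@dataclass
class NullEnsemble:
    """Observed values plus streaming null-rank counts per metric/cell."""

    cells: pd.Index
    n_reps: int
    observed: dict[str, np.ndarray]
    n_ge: dict[str, np.ndarray]  # null >= observed, per cell
    n_le: dict[str, np.ndarray]  # null <= observed, per cell
    null_sum: dict[str, np.ndarray]
    coords: pd.DataFrame | None = None
    trade_acceptance: list[int] = field(default_factory=list)

    def null_mean(self, metric: str) -> pd.Series:
        self._check(metric)
        return pd.Series(self.null_sum[metric] / self.n_reps, index=self.cells)

    def _check(self, metric: str):
        if metric not in self.observed:
            raise UnknownMetricError(metric)


def _cell_metrics(X, membership, is_internal, L, L_eq, convention):
    """PD/RPD/PE/RPE per cell for one (possibly randomized) matrix."""
    Xf = X.astype(np.float32)
    Mf = membership.astype(np.float32)
    counts = Xf @ Mf
    inc = counts > 0
    if convention == "crown":
        richness = X.sum(axis=1).astype(np.float32)
        inc &= ~(is_internal[None, :] & (counts == richness[:, None]))
    R = inc.sum(axis=0).astype(float)
    safe_R = np.maximum(R, 1.0)
    weights = np.column_stack(
        [L, L_eq, np.where(R > 0, L / safe_R, 0.0),
         np.where(R > 0, L_eq / safe_R, 0.0)]
    )
    vals = inc.astype(np.float32) @ weights
    pd_, pd_eq, pe, pe_eq = vals.T
    with np.errstate(invalid="ignore", divide="ignore"):
        rpd = np.where(pd_eq > 0, pd_ / pd_eq, np.nan)
        rpe = np.where(pe_eq > 0, pe / pe_eq, np.nan)
    return {
        "TR": X.sum(axis=1).astype(float),
        "PD": pd_.astype(float),
        "RPD": rpd.astype(float),
        "PE_actual": pe.astype(float),
        "PE_equalized": pe_eq.astype(float),
        "RPE": rpe.astype(float),
    }


def build_null_ensemble(
    matrix, tree, config: RandomizationConfig, convention: str = "root"
) -> NullEnsemble:
    """Run the 999-trial (by default) randomization for all metrics.

    Each replicate draws an independent fixed-margin randomization and
    recomputes every metric with the original branch lengths but the
    randomized cell sets.  The whole ensemble is a pure function of
    (matrix, tree, config.seed).
    """
    taxa = list(matrix.taxa)
    _, L, membership, is_internal = tree_arrays(tree, taxa)
    n_counted = len(counted_nodes(tree))
    L_eq = np.full_like(L, L.sum() / n_counted)
    X = matrix.values
    observed = _cell_metrics(X, membership, is_internal, L, L_eq, convention)
    n_cells = X.shape[0]
    n_ge = {m: np.zeros(n_cells, dtype=np.int64) for m in ENSEMBLE_METRICS}
    n_le = {m: np.zeros(n_cells, dtype=np.int64) for m in ENSEMBLE_METRICS}
    null_sum = {m: np.zeros(n_cells, dtype=float) for m in ENSEMBLE_METRICS}
    # ties must be exact recomputations, not float jitter: compare with a
    # tolerance proportional to the observed value
    tol = {
        m: 1e-9 * np.maximum(1.0, np.abs(observed[m]))
        for m in ENSEMBLE_METRICS
    }
    n_trades = _burn_in(int(X.sum()), config.burn_in_swaps_factor)
    rep_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_reps, dtype=np.uint32
    )
    acceptance = []
    for r in range(config.n_reps):
        Xr = X.copy()
        acceptance.append(curveball(Xr, n_trades, int(rep_seeds[r])))
        null = _cell_metrics(Xr, membership, is_internal, L, L_eq, convention)
        for m in ENSEMBLE_METRICS:
            n_ge[m] += null[m] >= observed[m] - tol[m]
            n_le[m] += null[m] <= observed[m] + tol[m]
            null_sum[m] += null[m]
    return NullEnsemble(
        cells=matrix.cell_ids,
        n_reps=config.n_reps,
        observed=observed,
        n_ge=n_ge,
        n_le=n_le,
        null_sum=null_sum,
        coords=matrix.cells,
        trade_acceptance=acceptance,
    )


@dataclass
class SignificanceSurface:
    """Per-cell rank p-values and a significance flag at a stated alpha."""

    metric: str
    tail: str
    alpha: float
    p_high: pd.Series
    p_low: pd.Series
    flag: pd.Series  # in {"sig-high", "sig-low", "ns"}
    observed: pd.Series | None = None
    coords: pd.DataFrame | None = None

    @property
    def cells(self) -> pd.Index:
        return self.p_high.index

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "metric": self.metric,
                "observed": self.observed,
                "p_high": self.p_high,
                "p_low": self.p_low,
                "flag": self.flag,
            }
        )
        if self.coords is not None:
            df.insert(0, "y", self.coords["y"])
            df.insert(0, "x", self.coords["x"])
        df.index.name = "cell_id"
        return df


def significance_ranks(
    ensemble: NullEnsemble, metric: str, tail: str = "two",
    alpha: float = 0.05,
) -> SignificanceSurface:
    """Rank-based p-values: p_high = (1 + #{null >= obs}) / (1 + n_reps).

    ``tail="two"`` flags sig-high when p_high <= alpha/2 and sig-low
    when p_low <= alpha/2 (equal-tail split); ``tail="high"`` flags
    sig-high when p_high <= alpha.
    """
    ensemble._check(metric)
    if tail not in ("two", "high"):
        raise ValueError(f"unknown tail {tail!r}")
    denom = 1 + ensemble.n_reps
    p_high = pd.Series((1 + ensemble.n_ge[metric]) / denom, index=ensemble.cells)
    p_low = pd.Series((1 + ensemble.n_le[metric]) / denom, index=ensemble.cells)
    cut = alpha / 2 if tail == "two" else alpha
    flag = pd.Series("ns", index=ensemble.cells, dtype=object)
    flag[p_high <= cut] = "sig-high"
    if tail == "two":
        flag[p_low <= cut] = "sig-low"
    return SignificanceSurface(
        metric=metric,
        tail=tail,
        alpha=alpha,
        p_high=p_high,
        p_low=p_low,
        flag=flag,
        observed=pd.Series(ensemble.observed[metric], index=ensemble.cells),
        coords=ensemble.coords,
    )


@dataclass
class CanapeMap:
    """Per-cell endemism category; categories are mutually exclusive."""

    categories: pd.Series
    coords: pd.DataFrame | None = None

    @property
    def cells(self) -> pd.Index:
        return self.categories.index

    def counts(self) -> pd.Series:
        return self.categories.value_counts().reindex(CATEGORIES, fill_value=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"category": self.categories})
        if self.coords is not None:
            df.insert(0, "y", self.coords["y"])
            df.insert(0, "x", self.coords["x"])
        df.index.name = "cell_id"
        return df


def canape_classify(
    pe_sig_actual: SignificanceSurface,
    pe_sig_equalized: SignificanceSurface,
    rpe_sig: SignificanceSurface,
    config: RandomizationConfig,
    either_tree: bool = False,
) -> CanapeMap:
    """Two-step CANAPE categorization from PE and RPE significance.

    Step one passes cells with one-tailed-high PE p <= alpha (actual
    tree by default; with ``either_tree`` the smaller of the actual and
    comparison-tree p-values is used).  Step two sends RPE-significant
    cells to paleo (high) or neo (low); the remainder are mixed, or
    super when the step-one p is at or below ``alpha_super``.
    """
    cells = pe_sig_actual.cells
    for surf in (pe_sig_equalized, rpe_sig):
        if not cells.equals(surf.cells):
            raise AlignmentError("significance surfaces cover different cells")
    alpha = config.alpha_two_tailed
    step1_p = pe_sig_actual.p_high
    if either_tree:
        step1_p = np.minimum(step1_p, pe_sig_equalized.p_high)
    passes = step1_p <= alpha
    rpe_high = rpe_sig.p_high <= alpha / 2
    rpe_low = rpe_sig.p_low <= alpha / 2
    cats = pd.Series("not-significant", index=cells, dtype=object)
    cats[passes & rpe_high] = "paleo"
    cats[passes & rpe_low & ~rpe_high] = "neo"
    mixed = passes & ~rpe_high & ~rpe_low
    cats[mixed] = "mixed"
    cats[mixed & (step1_p <= config.alpha_super)] = "super"
    return CanapeMap(categories=cats, coords=pe_sig_actual.coords)
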