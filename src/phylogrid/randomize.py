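"""Fixed-margin randomization of the cell x taxon matrix.

The null model assigns taxa randomly to grid cells under two hard
constraints: each cell keeps its observed richness (row sum) and each
taxon keeps its observed range size (column sum).  On the tree side
this amounts to drawing, for every cell, a random set of the same
number of terminals.

The sampler is a curveball (trade-based) Markov chain: repeatedly pick
two cells and randomly re-deal the taxa not shared between them.  Every
trade preserves both margins exactly and the chain is irreducible on
the fixed-margin polytope.  Each emitted null matrix comes from an
independently seeded chain started at the observed matrix and burned in
for ``burn_in_swaps_factor x (number of presences)`` trades.

The trade loop is compiled with numba; the same kernel backs
:func:`randomize_matrix`, the null ensembles, and the synthetic
null-dataset generator, so all of them draw from one sampler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from ._errors import InvalidParameterError

__all__ = ["RandomizationConfig", "randomize_matrix", "curveball"]


@dataclass
class RandomizationConfig:
    """Null-model settings: 999 trials and the printed alpha levels."""

    n_reps: int = 999
    alpha_two_tailed: float = 0.05
    alpha_super: float = 0.01
    seed: int = 0
    burn_in_swaps_factor: float = 1.0

    def __post_init__(self):
        if self.n_reps < 1:
            raise InvalidParameterError("n_reps must be >= 1")
        if not (0.0 < self.alpha_two_tailed < 1.0):
            raise InvalidParameterError("alpha_two_tailed must be in (0, 1)")
        if not (self.alpha_super < self.alpha_two_tailed):
            raise InvalidParameterError(
                "alpha_super must be stricter than alpha_two_tailed"
            )
        if self.burn_in_swaps_factor <= 0:
            raise InvalidParameterError("burn_in_swaps_factor must be > 0")


@njit(cache=True)
def _curveball_kernel(X, n_trades, seed):  # pragma: no cover - compiled
    np.random.seed(seed)
    n_rows, n_cols = X.shape
    only_a = np.empty(n_cols, np.int64)
    only_b = np.empty(n_cols, np.int64)
    pool = np.empty(2 * n_cols, np.int64)
    accepted = 0
    for _ in range(n_trades):
        a = np.random.randint(0, n_rows)
        b = np.random.randint(0, n_rows - 1)
        if b >= a:
            b += 1
        na = 0
        nb = 0
        for j in range(n_cols):
            xa = X[a, j]
            xb = X[b, j]
            if xa and not xb:
                only_a[na] = j
                na += 1
            elif xb and not xa:
                only_b[nb] = j
                nb += 1
        if na == 0 or nb == 0:
            continue
        ntot = na + nb
        pool[:na] = only_a[:na]
        pool[na:ntot] = only_b[:nb]
        # partial Fisher-Yates: a uniform na-subset ends up in pool[:na]
        for i in range(na):
            k = i + np.random.randint(0, ntot - i)
            tmp = pool[i]
            pool[i] = pool[k]
            pool[k] = tmp
        for i in range(ntot):
            j = pool[i]
            if i < na:
                X[a, j] = True
                X[b, j] = False
            else:
                X[a, j] = False
                X[b, j] = True
        accepted += 1
    return accepted


def curveball(X: np.ndarray, n_trades: int, seed: int) -> int:
    """Run seeded curveball trades in place on a boolean matrix.

    Returns the number of accepted (state-changing) trades.  Row and
    column sums are invariant under every trade.
    """
    if X.shape[0] < 2 or X.shape[1] < 1 or n_trades < 1:
        return 0
    return int(_curveball_kernel(X, int(n_trades), int(seed) % (2**32)))


def _burn_in(n_presences: int, factor: float) -> int:
    return max(1, int(round(factor * n_presences)))


def randomize_matrix(matrix, seed: int, burn_in_swaps_factor: float = 1.0):
    """One draw from the fixed-margin null, seeded and reproducible.

    Row sums (cell richness) and column sums (taxon ranges) of the
    output equal those of the input exactly, for every seed.
    """
    X = matrix.values.copy()
    curveball(X, _burn_in(int(X.sum()), burn_in_swaps_factor), seed)
    return matrix.with_data(X)
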