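"""Permutation nulls and empirical p-values for relative potencies.

The null model destroys any compound- or target-structure in the matrix by
uniformly shuffling the measured pK_d values across the measured cells (the
mask is kept).  Recomputing L or G on each shuffled matrix and pooling the
per-pair values over all shuffles gives one global background sample per
statistic; an observed value's empirical p-value is the fraction of the
background at least as large (upper tail).

Row- or column-label permutation modes exist for auditing, but both leave
every compound spectrum intact up to relabeling, so L and G — row-wise
statistics — are unchanged and the null is degenerate; cell-wise shuffling
is the default for that reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .activity_matrix import BioactivityMatrix
from .potency import _relative_potencies

__all__ = ["PermutationNull", "permute_matrix", "null_distribution", "empirical_pvalues"]

PermuteMode = Literal["cells", "rows", "columns"]


def permute_matrix(
    m: BioactivityMatrix,
    seed: int | np.random.Generator,
    mode: PermuteMode = "cells",
) -> BioactivityMatrix:
    """Return a shuffled copy of a matrix; the mask never moves.

    ``"cells"`` permutes the multiset of measured values uniformly over the
    measured positions; ``"rows"``/``"columns"`` permute compound/target
    labels instead (value rows/columns move with their labels).
    """
    if m.n_pairs < 2:
        raise ValueError("need at least 2 measured entries to permute")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mode == "cells":
        vals = m.values.copy()
        ci, tj = np.nonzero(m.mask)
        vals[ci, tj] = rng.permutation(vals[ci, tj])
        return BioactivityMatrix(
            compounds=list(m.compounds),
            targets=list(m.targets),
            values=vals,
            mask=m.mask.copy(),
        )
    if mode == "rows":
        order = rng.permutation(len(m.compounds))
        return BioactivityMatrix(
            compounds=[m.compounds[i] for i in order],
            targets=list(m.targets),
            values=m.values[order].copy(),
            mask=m.mask[order].copy(),
        )
    if mode == "columns":
        order = rng.permutation(len(m.targets))
        return BioactivityMatrix(
            compounds=list(m.compounds),
            targets=[m.targets[j] for j in order],
            values=m.values[:, order].copy(),
            mask=m.mask[:, order].copy(),
        )
    raise ValueError(f"unknown permutation mode: {mode!r}")


@dataclass
class PermutationNull:
    """Pooled background sample of a relative-potency statistic.

    ``values`` holds n_perm × (number of measured pairs) draws; it is stored
    sorted so p-value lookup is a binary search.
    """

    statistic: Literal["local", "global"]
    h: int | None
    n_perm: int
    values: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.size


def null_distribution(
    m: BioactivityMatrix,
    statistic: Literal["local", "global"],
    h: int = 5,
    n_perm: int = 10_000,
    seed: int = 0,
    mode: PermuteMode = "cells",
) -> PermutationNull:
    """Build the pooled permutation null of L or G for a matrix.

    Each of ``n_perm`` shuffles recomputes the statistic for every measured
    pair (pairs whose compound has a single measured target are undefined
    and excluded from the pool).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be a positive integer")
    if statistic not in ("local", "global"):
        raise ValueError(f"statistic must be 'local' or 'global', got {statistic!r}")
    rng = np.random.default_rng(seed)
    h_eff = h if statistic == "local" else None
    pool = []
    for _ in range(n_perm):
        perm = permute_matrix(m, rng, mode=mode)
        grid = _relative_potencies(perm, h_eff)
        vals = grid[perm.mask]
        pool.append(vals[np.isfinite(vals)])
    return PermutationNull(
        statistic=statistic,
        h=h if statistic == "local" else None,
        n_perm=n_perm,
        values=np.concatenate(pool),
        seed=seed,
    )


def empirical_pvalues(
    observed,
    null: PermutationNull,
    tail: Literal["upper", "lower"] = "upper",
    pseudocount: bool = False,
):
    """Empirical p-values of observed statistics against a pooled null.

    Upper tail (default): p = #{b in null : b ≥ x} / |null| — large relative
    potency is the interesting direction.  Lower tail uses ≤.  With
    ``pseudocount`` the standard (r + 1)/(N + 1) correction keeps p > 0.
    """
    if len(null) == 0:
        raise ValueError("null distribution is empty")
    x = np.asarray(observed, dtype=float)
    n = len(null)
    if tail == "upper":
        below = np.searchsorted(null.values, x, side="left")
        count = n - below
    elif tail == "lower":
        count = np.searchsorted(null.values, x, side="right")
    else:
        raise ValueError(f"tail must be 'upper' or 'lower', got {tail!r}")
    if pseudocount:
        p = (count + 1) / (n + 1)
    else:
        p = count / n
    return p if p.ndim else float(p)
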