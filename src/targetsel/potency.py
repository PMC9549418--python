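"""Absolute and relative potency scoring.

For a compound c with bioactivity spectrum B_c and a target t with measured
affinity K_{c,t} (pK_d):

* absolute potency  K_{c,t} — the pK_d itself;
* global relative potency  G_{c,t} = K_{c,t} − mean(B_c \\ {K_{c,t}});
* local relative potency   L_{c,t} = K_{c,t} − mean of the h spectrum values
  nearest to K_{c,t} in activity (the target itself excluded);
* integrated selectivity score  S = α·L + (1−α)·G.

All statistics are differences of pK_d values, so they are invariant under
adding a constant to a compound's whole spectrum.  Compounds with a single
measured target have no "other targets" to compare against; their pairs
carry NaN and are reported as excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_matrix import ActivityVector, BioactivityMatrix

__all__ = [
    "PotencyTable",
    "neighbor_targets",
    "local_relative_potency",
    "global_relative_potency",
    "integrated_score",
    "score_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_H = 5
DEFAULT_ALPHA = 0.5


@dataclass
class PotencyTable:
    """Per-pair potency statistics for the measured pairs of one matrix.

    ``table`` has one row per measured pair with columns
    ``compound, target, K, L, G, S``; L, G, S are NaN for compounds with a
    single measured target (``excluded`` lists them).
    """

    table: pd.DataFrame
    h: int
    alpha: float

    @property
    def excluded(self) -> list[str]:
        """Compounds whose pairs carry undefined relative potencies."""
        bad = self.table.loc[self.table["G"].isna(), "compound"]
        return sorted(set(bad))

    def pair(self, compound: str, target: str) -> pd.Series:
        sel = self.table[
            (self.table["compound"] == compound) & (self.table["target"] == target)
        ]
        if sel.empty:
            raise KeyError(f"pair ({compound}, {target}) not measured")
        return sel.iloc[0]


def neighbor_targets(spectrum: ActivityVector, target: str, h: int) -> list[str]:
    """The h targets of a spectrum nearest in activity to ``target``.

    Distance is |ΔpK_d| between spectrum values; the reference target is
    never its own neighbor.  Ordering: ascending distance, distance ties
    broken by higher potency first, then lexicographic target id.  When the
    spectrum holds fewer than h other targets, all of them are returned.
    """
    if h < 1:
        raise ValueError("h must be a positive integer")
    if target not in spectrum.entries:
        raise KeyError(f"target {target!r} not in spectrum of {spectrum.axis_label!r}")
    if len(spectrum) < 2:
        raise ValueError(
            f"spectrum of {spectrum.axis_label!r} has a single entry; "
            "no neighbors exist"
        )
    ref = spectrum.entries[target]
    others = [(t, v) for t, v in spectrum.entries.items() if t != target]
    others.sort(key=lambda tv: (abs(tv[1] - ref), -tv[1], tv[0]))
    return [t for t, _ in others[: min(h, len(others))]]


def _relative_potencies(m: BioactivityMatrix, h: int | None) -> np.ndarray:
    """Per-cell L (h given) or G (h None); NaN where unmeasured or undefined.

    The local statistic needs, for every measured cell, the mean of the h
    nearest spectrum values under the (distance, −potency, id) ordering; this
    is done row-wise with a lexsort over the full pairwise-distance grid of
    the row, which is exact for the tie rules and fast enough for panels of a
    few hundred targets.
    """
    n_c, n_t = m.shape
    out = np.full((n_c, n_t), np.nan)
    # lexicographic rank of target ids, for the final tie-break
    id_rank = np.argsort(np.argsort(np.asarray(m.targets, dtype=object)))
    for i in range(n_c):
        cols = np.nonzero(m.mask[i])[0]
        k = cols.size
        if k < 2:
            if k == 1:
                logger.warning(
                    "compound %r has a single measured target; "
                    "relative potencies undefined",
                    m.compounds[i],
                )
            continue
        v = m.values[i, cols]
        if h is None:  # global: mean of all other measured values
            out[i, cols] = v - (v.sum() - v) / (k - 1)
            continue
        n_nb = min(h, k - 1)
        if h > k - 1:
            logger.warning(
                "compound %r: h=%d clamped to %d available neighbors",
                m.compounds[i], h, k - 1,
            )
        dist = np.abs(v[None, :] - v[:, None])
        np.fill_diagonal(dist, np.inf)  # self is never its own neighbor
        ranks = np.broadcast_to(id_rank[cols], (k, k))
        neg_v = np.broadcast_to(-v, (k, k))
        order = np.lexsort((ranks, neg_v, dist), axis=-1)
        nb_vals = v[order[:, :n_nb]]
        out[i, cols] = v - nb_vals.mean(axis=1)
    return out


def local_relative_potency(m: BioactivityMatrix, h: int = DEFAULT_H) -> pd.DataFrame:
    """Long table (compound, target, L) for every measured pair.

    L = K minus the mean pK_d of the pair's h nearest-activity neighbor
    targets within the compound's spectrum; h clamps to the number of
    available neighbors.  NaN for compounds with a single measured target.
    """
    if h < 1:
        raise ValueError("h must be a positive integer")
    grid = _relative_potencies(m, h)
    return _grid_to_long(m, grid, "L")


def global_relative_potency(m: BioactivityMatrix) -> pd.DataFrame:
    """Long table (compound, target, G): K minus the mean of the compound's
    other measured pK_d values."""
    grid = _relative_potencies(m, None)
    return _grid_to_long(m, grid, "G")


def _grid_to_long(m: BioactivityMatrix, grid: np.ndarray, name: str) -> pd.DataFrame:
    ci, tj = np.nonzero(m.mask)
    return pd.DataFrame(
        {
            "compound": [m.compounds[i] for i in ci],
            "target": [m.targets[j] for j in tj],
            name: grid[ci, tj],
        }
    )


def integrated_score(L, G, alpha: float = DEFAULT_ALPHA):
    """S = α·L + (1−α)·G, elementwise over aligned per-pair values."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    return alpha * np.asarray(L, dtype=float) + (1.0 - alpha) * np.asarray(G, dtype=float)


def score_matrix(
    m: BioactivityMatrix,
    h: int = DEFAULT_H,
    alpha: float = DEFAULT_ALPHA,
) -> PotencyTable:
    """Compute K, L, G and S for every measured pair of a matrix."""
    if h < 1:
        raise ValueError("h must be a positive integer")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    L_grid = _relative_potencies(m, h)
    G_grid = _relative_potencies(m, None)
    ci, tj = np.nonzero(m.mask)
    L = L_grid[ci, tj]
    G = G_grid[ci, tj]
    table = pd.DataFrame(
        {
            "compound": [m.compounds[i] for i in ci],
            "target": [m.targets[j] for j in tj],
            "K": m.values[ci, tj],
            "L": L,
            "G": G,
            "S": alpha * L + (1.0 - alpha) * G,
        }
    )
    return PotencyTable(table=table, h=h, alpha=alpha)
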