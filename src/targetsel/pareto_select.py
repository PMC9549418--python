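"""Bi-objective selection of maximally selective compound–target pairs.

For each target, every compound with a measured affinity is a point
(K, R) — absolute potency and relative potency (local L or global G).  The
selective compounds for the target are those on the Pareto front of
"maximize K and maximize R" under weak dominance: a point is dropped iff
some other point is at least as good in both coordinates and strictly
better in one.  An ε-constraint sweep (maximize K subject to R ≥ ε, ε run
over the observed R values) traces the same front and serves as an
independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
import pandas as pd

from .activity_matrix import BioactivityMatrix
from .potency import PotencyTable

__all__ = ["Point", "SelectionResult", "pareto_front", "epsilon_sweep", "select_all"]

Statistic = Literal["local", "global"]


class Point(NamedTuple):
    compound: str
    K: float
    R: float


def _dominated_mask(K: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Weak-dominance flags: True where some point is ≥ in both coordinates
    and > in at least one.  Exact duplicates never dominate each other."""
    ge_K = K[:, None] <= K[None, :]
    ge_R = R[:, None] <= R[None, :]
    strict = (K[:, None] < K[None, :]) | (R[:, None] < R[None, :])
    return (ge_K & ge_R & strict).any(axis=1)


def pareto_front(points: list[Point]) -> list[Point]:
    """All points not weakly dominated, in sweep order (K descending,
    then R descending, then compound id).

    Duplicated coordinates of a non-dominated point are all retained.
    """
    if not points:
        raise ValueError("pareto_front requires a non-empty point list")
    pts = [Point(*p) for p in points]
    K = np.array([p.K for p in pts], dtype=float)
    R = np.array([p.R for p in pts], dtype=float)
    if not (np.all(np.isfinite(K)) and np.all(np.isfinite(R))):
        raise ValueError("point coordinates must be finite")
    keep = ~_dominated_mask(K, R)
    front = [p for p, k in zip(pts, keep) if k]
    front.sort(key=lambda p: (-p.K, -p.R, p.compound))
    return front


def epsilon_sweep(
    points: list[Point], constraint: Literal["ge", "lt"] = "ge"
) -> list[Point]:
    """ε-constraint scalarization of the bi-objective problem.

    For each ε in the sorted unique R values, take the maximal-K points
    among {R ≥ ε} (K-ties resolved toward maximal R) and return the union
    in the same ordering as :func:`pareto_front`.

    ``constraint="lt"`` applies the constraint as printed in some
    formulations, {R < ε}, which selects toward low relative potency; it is
    exposed for auditing only.
    """
    if not points:
        raise ValueError("epsilon_sweep requires a non-empty point list")
    pts = [Point(*p) for p in points]
    K = np.array([p.K for p in pts], dtype=float)
    R = np.array([p.R for p in pts], dtype=float)
    if not (np.all(np.isfinite(K)) and np.all(np.isfinite(R))):
        raise ValueError("point coordinates must be finite")
    chosen: set[int] = set()
    for eps in np.unique(R):
        feasible = R >= eps if constraint == "ge" else R < eps
        if not feasible.any():
            continue
        k_max = K[feasible].max()
        at_k = feasible & (K == k_max)
        r_best = R[at_k].max()
        winners = np.nonzero(at_k & (R == r_best))[0]
        chosen.update(winners.tolist())
    out = [pts[i] for i in sorted(chosen)]
    out.sort(key=lambda p: (-p.K, -p.R, p.compound))
    return out


@dataclass
class SelectionResult:
    """Per-target Pareto fronts and the induced selective/non-selective calls.

    ``calls``: long DataFrame (compound, target, K, R, selective) covering
    every measured pair with a defined relative potency.
    ``fronts``: target → front members in sweep order.
    """

    statistic: Statistic
    h: int | None
    calls: pd.DataFrame
    fronts: dict[str, list[Point]] = field(default_factory=dict)

    @property
    def selective_pairs(self) -> set[tuple[str, str]]:
        sel = self.calls[self.calls["selective"]]
        return set(zip(sel["compound"], sel["target"]))

    @property
    def n_selective(self) -> int:
        return int(self.calls["selective"].sum())


def select_all(
    m: BioactivityMatrix,
    scores: PotencyTable,
    statistic: Statistic = "local",
    min_pkd: float | None = None,
) -> SelectionResult:
    """Run per-target Pareto selection over a whole matrix.

    For every target t, the points are (compound, K_{c,t}, R_{c,t}) over
    compounds with measured K and defined R (R = L for ``statistic="local"``,
    G for ``"global"``); front members are the selective calls for t.
    ``min_pkd`` optionally drops pairs below an absolute-potency floor before
    optimization (no floor by default — baseline-only pairs are eligible).
    """
    if statistic not in ("local", "global"):
        raise ValueError(f"statistic must be 'local' or 'global', got {statistic!r}")
    rcol = "L" if statistic == "local" else "G"
    tab = scores.table[["compound", "target", "K", rcol]].rename(columns={rcol: "R"})
    tab = tab[np.isfinite(tab["R"])]
    if min_pkd is not None:
        tab = tab[tab["K"] >= min_pkd]
    fronts: dict[str, list[Point]] = {}
    selective: set[tuple[str, str]] = set()
    for target, grp in tab.groupby("target", sort=False):
        pts = [Point(c, float(k), float(r))
               for c, k, r in zip(grp["compound"], grp["K"], grp["R"])]
        front = pareto_front(pts)
        fronts[target] = front
        selective.update((p.compound, target) for p in front)
    for t in m.targets:
        fronts.setdefault(t, [])
    calls = tab.copy()
    calls["selective"] = [
        (c, t) in selective for c, t in zip(calls["compound"], calls["target"])
    ]
    calls = calls.reset_index(drop=True)
    return SelectionResult(
        statistic=statistic,
        h=scores.h if statistic == "local" else None,
        calls=calls,
        fronts=fronts,
    )
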