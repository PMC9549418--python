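"""Stability experiments: missing data, matrix size, and h-sensitivity.

Three experiments probe how stable the per-target Pareto calls are:

* missing-value injection — per target, a fixed fraction of measured
  compounds is masked (missing completely at random, independently across
  targets), and per-target recall is computed against the full-matrix calls;
* nested submatrix subsampling — increasingly large submatrices share one
  seed-fixed random ordering, so the 20% matrix is contained in the 40%
  matrix and so on, and per-pair consistency counts say in how many sizes a
  pair was called selective;
* h-sensitivity — local-statistic calls for a range of neighborhood sizes,
  scored by recall against the global-statistic calls (the h → |T|−1 limit,
  where L coincides with G).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .activity_matrix import BioactivityMatrix
from .pareto_select import SelectionResult, select_all
from .potency import score_matrix

__all__ = [
    "RecallReport",
    "ConsistencyCounts",
    "inject_missing",
    "subsample_matrix",
    "recall",
    "missing_value_experiment",
    "submatrix_experiment",
    "h_sensitivity",
]


@dataclass
class RecallReport:
    """Recall = TP / P of reference-selective pairs recovered by a call set.

    ``per_target`` is None for overall grouping; otherwise a DataFrame with
    columns TP, P, recall (NaN where the target has no reference positives).
    """

    TP: int
    P: int
    grouping: Literal["overall", "per_target"]
    per_target: pd.DataFrame | None = None

    @property
    def recall(self) -> float:
        return self.TP / self.P if self.P else float("nan")


@dataclass
class ConsistencyCounts:
    """Per-pair count of experimental conditions calling the pair selective."""

    counts: pd.DataFrame  # columns: compound, target, count
    conditions: list

    def as_matrix(self) -> pd.DataFrame:
        return self.counts.pivot(index="compound", columns="target",
                                 values="count").fillna(0).astype(int)


def inject_missing(
    m: BioactivityMatrix, rate: float, seed: int | np.random.Generator
) -> BioactivityMatrix:
    """Mask ⌈rate·n⌉ of each target's measured compounds, independently per
    target (MCAR).  rate ∈ [0, 1)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError(f"missing rate must lie in [0, 1), got {rate}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mask = m.mask.copy()
    if rate > 0:
        for j in range(len(m.targets)):
            measured = np.nonzero(mask[:, j])[0]
            n_drop = math.ceil(rate * measured.size)
            drop = rng.choice(measured, size=n_drop, replace=False)
            mask[drop, j] = False
    return BioactivityMatrix(
        compounds=list(m.compounds),
        targets=list(m.targets),
        values=m.values.copy(),
        mask=mask,
    )


def subsample_matrix(
    m: BioactivityMatrix, frac: float, seed: int | np.random.Generator
) -> BioactivityMatrix:
    """Keep the first ⌈frac·|C|⌉ compounds and ⌈frac·|T|⌉ targets of a
    seed-fixed random ordering, so smaller fractions nest inside larger ones
    taken with the same seed."""
    if not 0.0 < frac <= 1.0:
        raise ValueError(f"frac must lie in (0, 1], got {frac}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    c_order = rng.permutation(len(m.compounds))
    t_order = rng.permutation(len(m.targets))
    n_c = math.ceil(frac * len(m.compounds))
    n_t = math.ceil(frac * len(m.targets))
    if n_c < 2 or n_t < 2:
        raise ValueError(
            f"frac {frac} leaves a degenerate {n_c}×{n_t} matrix"
        )
    return m.subset(
        compounds=[m.compounds[i] for i in sorted(c_order[:n_c])],
        targets=[m.targets[j] for j in sorted(t_order[:n_t])],
    )


def recall(
    calls: SelectionResult,
    reference: SelectionResult,
    grouping: Literal["overall", "per_target"] = "overall",
    restrict_universe: bool = True,
) -> RecallReport:
    """Fraction of reference-selective pairs recovered.

    With ``restrict_universe`` (default) the positives P are limited to the
    pairs evaluable in ``calls`` (its measured-pair universe) — comparing
    like with like.  Without it, every reference-selective pair counts, so a
    pair that has been masked out of ``calls``' matrix scores as a miss;
    this is the accounting of the missing-value experiment, where losing a
    selective pair to missingness *is* the failure being measured.
    """
    call_universe = set(zip(calls.calls["compound"], calls.calls["target"]))
    ref_universe = set(zip(reference.calls["compound"], reference.calls["target"]))
    if not call_universe:
        raise ValueError("calls contain no evaluable pairs")
    if not call_universe <= ref_universe:
        raise ValueError("calls' pair universe is not contained in the reference's")
    if restrict_universe:
        ref_sel = reference.selective_pairs & call_universe
    else:
        ref_sel = reference.selective_pairs
    tp_pairs = calls.selective_pairs & ref_sel
    if grouping == "overall":
        return RecallReport(TP=len(tp_pairs), P=len(ref_sel), grouping="overall")
    targets = sorted({t for _, t in ref_universe})
    rows = []
    for t in targets:
        p = sum(1 for pair in ref_sel if pair[1] == t)
        tp = sum(1 for pair in tp_pairs if pair[1] == t)
        rows.append((t, tp, p, tp / p if p else float("nan")))
    per_target = pd.DataFrame(rows, columns=["target", "TP", "P", "recall"])
    return RecallReport(
        TP=len(tp_pairs), P=len(ref_sel), grouping="per_target", per_target=per_target
    )


def _calls_for(m: BioactivityMatrix, statistic: str, h: int) -> SelectionResult:
    return select_all(m, score_matrix(m, h=h), statistic=statistic)


def missing_value_experiment(
    m: BioactivityMatrix,
    rates: Sequence[float] = (0.2, 0.4, 0.6, 0.8),
    statistic: Literal["local", "global"] = "local",
    h: int = 5,
    seed: int = 0,
    reps: int = 1,
) -> tuple[ConsistencyCounts, list[tuple[float, RecallReport]]]:
    """Inject each missing rate (``reps`` independent replicates), re-run the
    selection, and report per-target recall against the full-matrix calls
    plus per-pair consistency counts across all conditions."""
    rng = np.random.default_rng(seed)
    reference = _calls_for(m, statistic, h)
    counter: dict[tuple[str, str], int] = {}
    reports: list[tuple[float, RecallReport]] = []
    conditions = []
    for rate in rates:
        for _ in range(reps):
            sub = inject_missing(m, rate, rng)
            calls = _calls_for(sub, statistic, h)
            reports.append((
                rate,
                recall(calls, reference, grouping="per_target",
                       restrict_universe=False),
            ))
            for pair in calls.selective_pairs:
                counter[pair] = counter.get(pair, 0) + 1
            conditions.append(rate)
    counts = pd.DataFrame(
        [(c, t, n) for (c, t), n in sorted(counter.items())],
        columns=["compound", "target", "count"],
    )
    return ConsistencyCounts(counts=counts, conditions=conditions), reports


def submatrix_experiment(
    m: BioactivityMatrix,
    fracs: Sequence[float] = (0.2, 0.4, 0.6, 0.8, 1.0),
    statistic: Literal["local", "global"] = "local",
    h: int = 5,
    seed: int = 0,
) -> ConsistencyCounts:
    """Aligned sum of binary selective-call matrices across nested
    submatrices; a pair present in all sizes can score up to len(fracs)."""
    counter: dict[tuple[str, str], int] = {}
    for frac in fracs:
        sub = m if frac == 1.0 else subsample_matrix(m, frac, seed)
        calls = _calls_for(sub, statistic, h)
        for pair in calls.selective_pairs:
            counter[pair] = counter.get(pair, 0) + 1
    counts = pd.DataFrame(
        [(c, t, n) for (c, t), n in sorted(counter.items())],
        columns=["compound", "target", "count"],
    )
    return ConsistencyCounts(counts=counts, conditions=list(fracs))


def h_sensitivity(
    m: BioactivityMatrix,
    h_values: Sequence[int] = (1, 5, 20, 100),
    grouping: Literal["overall", "per_target"] = "per_target",
) -> list[tuple[int, RecallReport]]:
    """Recall of local-statistic calls at each h against the
    global-statistic calls taken as ground truth."""
    reference = select_all(m, score_matrix(m), statistic="global")  # G ignores h
    out = []
    for h in h_values:
        calls = _calls_for(m, "local", h)
        out.append((h, recall(calls, reference, grouping=grouping)))
    return out
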