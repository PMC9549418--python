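"""Classical selectivity metrics for comparison with the target-specific score.

Per-compound (target-agnostic) metrics:

* standard selectivity score — number of targets bound above a pK_d cutoff
  (default 7, i.e. K_d < 100 nM);
* Gini coefficient of the compound's activity signal across targets (high =
  concentrated on few targets = selective);
* selectivity entropy — Shannon entropy (nats) of the K_a-proportional
  distribution of binding across targets (low = selective);
* summaries of the target-specific score: mean S across targets and the
  number of targets the compound is called selective for.

Per-pair metric:

* partition index — the fraction of a compound's total association-constant
  (K_a = 1/K_d) mass on a chosen reference target, reported also as
  −log10 (small −log10 = selective for that target).

For side-by-side plots all per-compound metrics can be z-scaled to zero
mean / unit sd and sign-oriented so that smaller always means more selective.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activity_matrix import BioactivityMatrix
from .pareto_select import SelectionResult
from .potency import PotencyTable

__all__ = [
    "standard_score",
    "gini_coefficient",
    "selectivity_entropy",
    "partition_index",
    "summarize_target_agnostic",
    "zscale",
    "metric_table",
    "partition_index_table",
]

BASELINE_PKD = 5.0


def standard_score(
    m: BioactivityMatrix, cutoff_pkd: float = 7.0, strict: bool = False
) -> pd.Series:
    """Per-compound count of measured targets with pK_d ≥ cutoff
    (or > cutoff when ``strict``)."""
    vals = np.where(m.mask, m.values, -np.inf)
    hits = vals > cutoff_pkd if strict else vals >= cutoff_pkd
    return pd.Series(hits.sum(axis=1), index=m.compounds, name="standard_score")


def gini_coefficient(activity) -> float:
    """Gini coefficient of a nonnegative activity signal.

    Mean-absolute-difference form: Σ_ij |x_i − x_j| / (2 n² mean).  All-zero
    input returns 0 by convention (perfect equality).
    """
    x = np.asarray(activity, dtype=float)
    if x.size == 0:
        raise ValueError("gini_coefficient needs at least one value")
    if np.any(x < 0):
        raise ValueError("activity signal must be nonnegative")
    total = x.sum()
    if total == 0:
        return 0.0
    # O(n log n) via the sorted-rank identity, equal to the double sum
    xs = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2 * ranks - n - 1) @ xs / (n * total))


def compound_gini(m: BioactivityMatrix, compound: str,
                  baseline_pkd: float = BASELINE_PKD) -> float:
    """Gini of a compound's rectified signal max(pK_d − baseline, 0)."""
    spec = m.compound_spectrum(compound)
    return gini_coefficient(np.maximum(spec.values() - baseline_pkd, 0.0))


def _ka_fractions(pkd: np.ndarray) -> np.ndarray:
    """K_a-proportional weights φ_t = 10^pK_d / Σ 10^pK_d, overflow-safe."""
    shifted = pkd - pkd.max()
    ka = 10.0 ** shifted
    return ka / ka.sum()


def selectivity_entropy(m: BioactivityMatrix, compound: str) -> float:
    """Shannon entropy (nats) of the compound's K_a-proportional target
    distribution; 0 for a single measured target, ln n for a uniform spread."""
    spec = m.compound_spectrum(compound)
    if len(spec) == 0:
        raise ValueError(f"compound {compound!r} has no measured targets")
    phi = _ka_fractions(spec.values())
    nz = phi[phi > 0]
    return float(-(nz * np.log(nz)).sum())


def partition_index(
    m: BioactivityMatrix, compound: str, reference_target: str
) -> tuple[float, float]:
    """Fraction of the compound's K_a mass on a reference target.

    Returns (P, −log10 P) where P = K_a(ref) / Σ_t K_a(t) over the
    compound's measured targets, reference included.  P near 1 (−log10 near
    0) means the compound's binding is concentrated on the reference.
    """
    spec = m.compound_spectrum(compound)
    if reference_target not in spec.entries:
        raise KeyError(
            f"target {reference_target!r} not measured for compound {compound!r}"
        )
    phi = _ka_fractions(spec.values())
    idx = list(spec.entries).index(reference_target)
    p = float(phi[idx])
    return p, float(-np.log10(p))


def partition_index_table(m: BioactivityMatrix) -> pd.DataFrame:
    """Per-pair partition index over all measured pairs: long DataFrame
    (compound, target, partition_index, neglog10_partition_index)."""
    rows = []
    for c in m.compounds:
        spec = m.compound_spectrum(c)
        if len(spec) == 0:
            continue
        phi = _ka_fractions(spec.values())
        for (t, _), p in zip(spec, phi):
            rows.append((c, t, float(p), float(-np.log10(p))))
    return pd.DataFrame(
        rows, columns=["compound", "target", "partition_index",
                       "neglog10_partition_index"]
    )


def summarize_target_agnostic(
    scores: PotencyTable, calls: SelectionResult
) -> pd.DataFrame:
    """Per-compound mean integrated score and number of selective targets."""
    mean_s = scores.table.groupby("compound", sort=False)["S"].mean()
    n_sel = (
        calls.calls.groupby("compound", sort=False)["selective"].sum().astype(int)
    )
    out = pd.DataFrame({"mean_selectivity_score": mean_s})
    out["n_selective_targets"] = n_sel.reindex(out.index).fillna(0).astype(int)
    return out


def zscale(metric, larger_means_selective: bool) -> np.ndarray:
    """Standardize to zero mean / unit population sd, sign-oriented so that
    smaller values mean more selective compounds."""
    x = np.asarray(metric, dtype=float)
    if x.size < 2:
        raise ValueError("zscale needs at least 2 values")
    sd = x.std()  # population sd, so tiny inputs stay well-defined
    if sd == 0:
        raise ValueError("zscale undefined for zero-variance input")
    z = (x - x.mean()) / sd
    return -z if larger_means_selective else z


def metric_table(
    m: BioactivityMatrix,
    scores: PotencyTable,
    calls: SelectionResult,
    cutoff_pkd: float = 7.0,
) -> pd.DataFrame:
    """Assemble the per-compound metric panel with harmonized z-columns.

    Raw columns keep each metric's native direction; ``z_*`` columns are
    standardized and oriented so smaller = more selective everywhere.
    """
    idx = list(m.compounds)
    tab = pd.DataFrame(index=pd.Index(idx, name="compound"))
    tab["standard_score"] = standard_score(m, cutoff_pkd)
    tab["gini"] = [compound_gini(m, c) for c in idx]
    tab["entropy"] = [selectivity_entropy(m, c) for c in idx]
    summ = summarize_target_agnostic(scores, calls)
    tab["mean_selectivity_score"] = summ["mean_selectivity_score"].reindex(idx)
    tab["n_selective_targets"] = (
        summ["n_selective_targets"].reindex(idx).fillna(0).astype(int)
    )
    # orientation of the raw metrics: which direction means "selective"
    larger_is_selective = {
        "standard_score": False,   # many strong targets = promiscuous
        "gini": True,              # concentrated affinity = selective
        "entropy": False,          # spread-out affinity = promiscuous
        "mean_selectivity_score": True,
        # a compound called selective for many targets is broadly active
        "n_selective_targets": False,
    }
    for col, flip in larger_is_selective.items():
        vals = tab[col].to_numpy(dtype=float)
        if vals.std() == 0:
            tab[f"z_{col}"] = np.nan
        else:
            tab[f"z_{col}"] = zscale(vals, larger_means_selective=flip)
    return tab
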