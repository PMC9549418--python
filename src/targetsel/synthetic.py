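"""Synthetic bioactivity matrices with planted ground truth.

Emulates the structure of a large kinase profiling panel on the pK_d scale:
almost all cells sit at the no-activity baseline (pK_d = 5, i.e.
K_d = 10 µM), a handful of planted *selective* compounds each bind one
unique target strongly (pK_d ≈ 9), planted *promiscuous* compounds bind
many targets strongly, and every cell carries Gaussian measurement noise on
the log scale.  The planted (selective compound, its target) pairs are the
recoverable ground truth used throughout the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .activity_matrix import BioactivityMatrix

__all__ = ["SyntheticSpec", "generate_matrix"]


@dataclass
class SyntheticSpec:
    """Parameters of the generator.

    Defaults model a desk-scale panel: 20 compounds × 50 targets, 5 planted
    single-target compounds, 3 promiscuous compounds hitting 15 targets
    each, hits at pK_d 9.0 ± 0.3, assay noise sd 0.2 pK_d units.
    """

    n_compounds: int = 20
    n_targets: int = 50
    n_selective: int = 5
    n_promiscuous: int = 3
    k_high: int = 15
    baseline_pkd: float = 5.0
    hit_pkd_mean: float = 9.0
    hit_pkd_sd: float = 0.3
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_selective + self.n_promiscuous > self.n_compounds:
            raise ValueError("more planted compounds than compounds")
        if self.n_selective > self.n_targets:
            raise ValueError(
                "each selective compound needs its own target: "
                f"{self.n_selective} > {self.n_targets}"
            )
        if self.k_high > self.n_targets:
            raise ValueError("k_high exceeds the number of targets")
        if min(self.hit_pkd_sd, self.noise_sd) < 0:
            raise ValueError("standard deviations must be nonnegative")
        if self.n_compounds < 1 or self.n_targets < 2:
            raise ValueError("need ≥1 compound and ≥2 targets")


def generate_matrix(
    spec: SyntheticSpec,
) -> tuple[BioactivityMatrix, set[tuple[str, str]]]:
    """Draw one matrix from a spec.

    Returns the matrix (fully measured) and the ground truth: the set of
    (selective compound, planted target) pairs.  Compounds are named C01…,
    targets T01…; the first ``n_selective`` compounds are the selective
    ones, the next ``n_promiscuous`` the promiscuous ones.
    """
    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(spec.n_compounds)), len(str(spec.n_targets)))
    compounds = [f"C{i + 1:0{width}d}" for i in range(spec.n_compounds)]
    targets = [f"T{j + 1:0{width}d}" for j in range(spec.n_targets)]

    values = np.full((spec.n_compounds, spec.n_targets), spec.baseline_pkd)
    truth: set[tuple[str, str]] = set()

    # one unique strong target per selective compound
    sel_targets = rng.choice(spec.n_targets, size=spec.n_selective, replace=False)
    for i, j in enumerate(sel_targets):
        values[i, j] = rng.normal(spec.hit_pkd_mean, spec.hit_pkd_sd)
        truth.add((compounds[i], targets[j]))

    # k_high strong targets per promiscuous compound (without replacement
    # within a compound; overlap across compounds allowed)
    for i in range(spec.n_selective, spec.n_selective + spec.n_promiscuous):
        hits = rng.choice(spec.n_targets, size=spec.k_high, replace=False)
        values[i, hits] = rng.normal(spec.hit_pkd_mean, spec.hit_pkd_sd,
                                     size=spec.k_high)

    values = values + rng.normal(0.0, spec.noise_sd, size=values.shape)
    m = BioactivityMatrix(
        compounds=compounds,
        targets=targets,
        values=values,
        mask=np.ones_like(values, dtype=bool),
    )
    return m, truth
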