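# Methods

## Data model

A `BioactivityMatrix` holds pK_d values for |C| compounds × |T| targets
with a boolean mask of measured cells.  pK_d (−log10 of K_d in molar) is
the one internal scale; loaders convert declared units (nM, µM, M) on
ingestion and there is no unit sniffing.  Missing data is represented only
by the mask — never by sentinel values — because the pK_d = 5 baseline of a
primary screen is a real measurement ("no activity at 10 µM"), not a gap.
Identifiers are case-sensitive, whitespace-trimmed strings; wide files can
be oriented either way via an explicit flag, since public kinase-panel
exports ship both ways.

## Potency decomposition

For a measured pair (c, t) with spectrum B_c:

* K — absolute potency, the pK_d itself;
* G = K − mean(B_c \ {K}) — global relative potency;
* L = K − mean of the h nearest spectrum values — local relative potency;
* S = α·L + (1−α)·G — integrated score, defaults h = 5, α = 0.5.

Neighborhood details that the formulas alone leave open, fixed here:

* the target is never its own neighbor (including it would drag L toward 0);
* neighbor distance is |ΔpK_d| in activity value, not rank adjacency, so
  duplicated values (the ubiquitous baseline 5) are distinct neighbors at
  distance 0;
* distance ties break toward the *higher-potency* neighbor first — the
  conservative direction, since averaging a stronger neighbor lowers L for
  borderline pairs — then lexicographic target id, making results
  deterministic and order-independent;
* h larger than the available neighbors clamps (with a logged warning)
  rather than dropping the compound, so the same formulas run unchanged on
  matrices with missing values;
* compounds with a single measured target have no reference set: their
  pairs carry NaN and are reported as excluded.

All three statistics are differences of pK_d values, hence exactly
invariant under adding a constant to a compound's whole spectrum; L with
h = |T|−1 equals G identically.  The local computation is vectorized per
row (a lexsort over the row's pairwise-distance grid encodes the tie rules
exactly); the test suite pins it to a naive per-pair loop at 1e−12.

## Bi-objective selection

Per target, each measured compound is a point (K, R) with R = L or G, and
the selective compounds are the Pareto front of "maximize both" under
*weak* dominance: p is dropped iff some q has K_q ≥ K_p and R_q ≥ R_p with
one inequality strict.  Exact coordinate duplicates of a front point are
all retained.  Choices worth stating:

* **Per-target scope.**  The optimization is solved independently for each
  target rather than once over all (c, t) jointly; per-target fronts are
  what a target-centric user needs, and a single global front would return
  a handful of pairs rather than a per-target ranking.
* **Constraint direction.**  The ε-sweep is implemented over {R ≥ ε} so
  that both objectives are maximized; a literal {R < ε} variant (which
  would select toward *low* relative potency) is exposed behind a flag for
  auditing only.
* **No activity floor.**  Baseline-only pairs are eligible; `min_pkd`
  opts into a potency floor.

The ε-sweep is implemented separately from the dominance filter and the
two (plus an O(n²) brute-force filter) are asserted equal on random point
sets with and without ties — a genuinely independent cross-check, since
ties are where the two formulations can silently diverge.

## Permutation significance

The null shuffles the multiset of measured values uniformly across the
measured cells (mask fixed), recomputes L or G for every pair, and pools
all values over n_perm shuffles (default 10,000) into one background per
statistic.  Empirical p = #{background ≥ observed}/N — the *upper* tail,
because large relative potency is the signal of interest; the lower-tail
variant and a (r+1)/(N+1) pseudocount are selectable.  Row- or
column-label permutation modes exist but are documented as degenerate: L
and G are functions of a compound's spectrum alone, and relabeling rows or
columns leaves every spectrum intact, so cell-wise shuffling is the only
mode that produces a non-trivial null.  Under the null the pooled G
p-values are approximately uniform (KS distance ≈ 0.02 at n_perm = 1,000
on a 20×50 panel, asserted < 0.05 in the acceptance tests); L's pooled
null is heavier-tailed at small h and its p-values are not expected to be
uniform.  No multiple-testing correction is applied.

## Baseline metrics

* **Standard score**: count of measured targets with pK_d ≥ cutoff
  (default 7); a strict-inequality switch exists because screen baselines
  sit exactly on round values.
* **Gini**: mean-absolute-difference form Σ|x_i−x_j|/(2n²x̄), computed on
  the rectified signal max(pK_d − 5, 0).  The metric was designed for
  percent-inhibition data and no canonical transform to K_d exists, so the
  baseline-anchored rectification is a documented, swappable choice and
  Gini is excluded from any exact external comparison.
* **Selectivity entropy**: Shannon entropy (in nats) of
  φ_t = K_a(t)/ΣK_a, K_a ∝ 10^pK_d (proportionality constants cancel; the
  computation is shifted by the row maximum so extreme pK_d cannot
  overflow).
* **Partition index**: P = K_a(ref)/ΣK_a per reference target, reported
  also as −log10 P; by construction Σ_t P(c,t) = 1 per compound and
  entropy = −Σ_t P ln P exactly, both asserted numerically.
* **Target-agnostic summaries** of the new score: mean S per compound and
  the number of targets the compound is called selective for.
* **z-harmonization**: (x−μ)/σ with population σ (so two-compound toys are
  defined), sign-oriented so that smaller always means more selective.
  Orientation per metric: standard score, entropy and the *selective-target
  count* flip with larger = broadly active — a compound picked up as
  selective for many targets is a promiscuous K-maximizer, as the planted
  archetypes in the tests show — while Gini and mean S flip with larger =
  selective.

## Robustness experiments

* **Missing values**: per target, ⌈rate·n⌉ of the measured compounds are
  masked, independently across targets (MCAR), at rates 0.2–0.8.  Recall of
  the full-matrix selective pairs is computed *without* restricting to the
  still-measured universe: losing a selective pair to missingness counts as
  a miss, which is the failure the experiment measures.  (The `recall`
  function's default mode restricts to the evaluable universe, the right
  accounting when comparing two methods on the same matrix, e.g. the
  h-sweep.)
* **Submatrix sizes**: one seed-fixed random ordering of compounds and of
  targets defines nested submatrices at fractions 0.2–1.0; per-pair
  consistency counts (in how many sizes a pair was called selective) are
  the stability readout.
* **h-sensitivity**: local-statistic calls at h ∈ {1, 5, 20, 100}, scored
  by recall against the global-statistic calls, whose h → |T|−1 limit they
  approach exactly (asserted recall = 1 at h = |T|−1).

## Synthetic panels

The generator emulates the gross structure of a kinase profiling panel:
an inert background at pK_d = 5, n_selective planted compounds with one
unique strong target each, n_promiscuous compounds with k_high strong
targets, hit strengths N(9.0, 0.3²) and Gaussian assay noise (sd 0.2) on
the log scale — the standard error model for affinity assays.  Defaults
(20×50, 5 selective, 3 promiscuous with k_high = 15) are deliberately
desk-scale; the acceptance script and tests run them in seconds.

What the synthetic panels do **not** model: correlation between related
targets (kinome phylogeny), compound-specific assay biases, non-random
missingness, and mixed readout types.  Passing tests therefore demonstrate
the method's behavior under clean MCAR/Gaussian conditions, not
performance on any real panel.  One consequence measured explicitly: with
15 hits among 50 targets, a promiscuous compound's *best* global relative
potency (≈ 3.6, its strongest hit against a mean dragged down by 35
baselines) overlaps the weakest planted pair's G (≈ N(4, 0.36)), so
planted pairs dominate promiscuous ones uniformly in L and S but only
per-target in G — the tests assert exactly that.

## Numerical and scale choices

Problem sizes in the default test and acceptance runs — 20×50 panels,
1,000 permutations, 20 seeds for recovery, 5 seeds × 4 rates for the
missing-data experiment — were chosen so the full suite completes in a few
seconds while keeping Monte-Carlo error well inside the asserted margins
(e.g. the KS bound 0.05 against a measured ≈ 0.02).  All randomness flows
through `numpy.random.default_rng` seeds; every experiment is
bit-reproducible under its seed, and the CLI logs the seed and parameters
of each run.

## Known limitations

* Relative potencies need ≥ 2 measured targets per compound; heavily
  missing rows degrade L before G (smaller effective neighborhoods), and
  the stability experiments suggest trusting results only up to ~20%
  missingness.
* Pareto-front *counts* are sensitive to the weak-dominance/tie rules
  when exact coordinate ties occur (real panels hold many tied baseline
  values); the rules above are deterministic and documented, but counts
  from implementations with other tie conventions will differ slightly.
* Empirical p-values are granular at 1/(n_perm·pairs) and are reported
  uncorrected for multiple testing.
* Mixed K_i/K_d/IC₅₀ panels must be harmonized upstream; the loaders
  accept a single declared unit only.
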