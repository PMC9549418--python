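import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from targetsel import (
    BioactivityMatrix,
    gini_coefficient,
    metric_table,
    partition_index,
    partition_index_table,
    score_matrix,
    select_all,
    selectivity_entropy,
    standard_score,
    summarize_target_agnostic,
    zscale,
)


def one_compound(pkds, targets=None):
    pkds = np.asarray(pkds, dtype=float)
    targets = targets or [f"t{j}" for j in range(pkds.size)]
    return BioactivityMatrix(["c"], targets, pkds[None, :])


class TestStandardScore:
    def test_counts_above_cutoff(self):
        m = one_compound([9.0, 7.5, 6.0])
        assert standard_score(m, 7.0)["c"] == 2

    def test_all_baseline_compound_scores_zero(self):
        m = one_compound([5.0] * 6)
        assert standard_score(m, 7.0)["c"] == 0

    def test_strict_inequality_excludes_boundary(self):
        m = one_compound([5.0, 5.0, 6.0])
        assert standard_score(m, 5.0)["c"] == 3
        assert standard_score(m, 5.0, strict=True)["c"] == 1

    def test_unmeasured_cells_never_counted(self):
        m = BioactivityMatrix(
            ["c"], ["t1", "t2"], np.array([[9.0, 9.0]]),
            np.array([[True, False]]),
        )
        assert standard_score(m, 7.0)["c"] == 1


class TestGini:
    def test_perfect_equality_is_zero(self):
        assert gini_coefficient([1, 1, 1, 1]) == pytest.approx(0.0)

    def test_half_and_half(self):
        assert gini_coefficient([0, 0, 1, 1]) == pytest.approx(0.5)

    def test_single_nonzero_is_maximal(self):
        assert gini_coefficient([0, 0, 0, 1]) == pytest.approx(0.75)  # (n−1)/n

    def test_matches_brute_force_double_sum(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            x = rng.random(int(rng.integers(2, 30)))
            brute = np.abs(x[:, None] - x[None, :]).sum() / (2 * x.size**2 * x.mean())
            assert gini_coefficient(x) == pytest.approx(brute, abs=1e-12)

    def test_all_zero_is_zero_by_convention(self):
        assert gini_coefficient([0.0, 0.0]) == 0.0

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            gini_coefficient([-1.0, 2.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1,
                    max_size=40))
    def test_bounded_in_unit_interval(self, xs):
        g = gini_coefficient(xs)
        assert 0.0 <= g < 1.0


class TestEntropy:
    def test_uniform_affinities_give_log_n(self):
        m = one_compound([7.0] * 4)
        assert selectivity_entropy(m, "c") == pytest.approx(np.log(4))

    def test_strong_versus_baseline_pair(self):
        # K_a ratio 1e4: φ ≈ {0.9999, 1e−4}; −Σ φ ln φ ≈ 0.001021
        m = one_compound([9.0, 5.0])
        assert selectivity_entropy(m, "c") == pytest.approx(0.001021, abs=1e-6)

    def test_single_target_is_degenerate_zero(self):
        m = one_compound([8.0])
        assert selectivity_entropy(m, "c") == 0.0

    def test_extreme_pkd_range_is_overflow_safe(self):
        m = one_compound([400.0, 5.0])
        assert np.isfinite(selectivity_entropy(m, "c"))


class TestPartitionIndex:
    def test_uniform_affinities_give_one_over_n(self):
        m = one_compound([6.5] * 5)
        p, _ = partition_index(m, "c", "t2")
        assert p == pytest.approx(1 / 5)

    def test_two_target_hand_calculation(self):
        # K_d 1 nM vs 100 nM → K_a 1e9 vs 1e7 → P = 100/101
        m = one_compound([9.0, 7.0], targets=["ref", "other"])
        p, neglog = partition_index(m, "c", "ref")
        assert p == pytest.approx(0.990099, abs=1e-6)
        assert neglog == pytest.approx(0.00432, abs=1e-5)

    def test_unmeasured_reference_is_error(self):
        m = BioactivityMatrix(
            ["c"], ["t1", "t2"], np.array([[9.0, 7.0]]),
            np.array([[True, False]]),
        )
        with pytest.raises(KeyError):
            partition_index(m, "c", "t2")

    def test_per_compound_sum_is_one(self, synth_default):
        m, _ = synth_default
        tab = partition_index_table(m)
        sums = tab.groupby("compound")["partition_index"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_entropy_equals_minus_sum_p_log_p(self, synth_default):
        m, _ = synth_default
        tab = partition_index_table(m)
        for c in m.compounds[:5]:
            p = tab.loc[tab["compound"] == c, "partition_index"].to_numpy()
            assert selectivity_entropy(m, c) == pytest.approx(
                -(p * np.log(p)).sum(), abs=1e-9
            )


class TestSummaries:
    def test_mean_score_and_selective_counts(self, synth_default):
        m, truth = synth_default
        scores = score_matrix(m, h=5)
        calls = select_all(m, scores, "local")
        summ = summarize_target_agnostic(scores, calls)
        # hand check one compound's mean against the raw table
        c = m.compounds[0]
        expect = scores.table.loc[scores.table["compound"] == c, "S"].mean()
        assert summ.loc[c, "mean_selectivity_score"] == pytest.approx(expect)
        assert (summ["n_selective_targets"] >= 0).all()

    def test_constant_spectrum_mean_is_zero(self, toy_matrix):
        scores = score_matrix(toy_matrix, h=2)
        calls = select_all(toy_matrix, scores, "local")
        summ = summarize_target_agnostic(scores, calls)
        assert summ.loc["c2", "mean_selectivity_score"] == pytest.approx(0.0)


class TestZScale:
    def test_population_sd_standardization(self):
        got = zscale([1, 2, 3], larger_means_selective=False)
        np.testing.assert_allclose(got, [-1.224745, 0, 1.224745], atol=1e-6)

    def test_orientation_flip(self):
        got = zscale([1, 2, 3], larger_means_selective=True)
        np.testing.assert_allclose(got, [1.224745, 0, -1.224745], atol=1e-6)

    def test_output_always_mean_zero_sd_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 9, size=40)
        z = zscale(x, larger_means_selective=True)
        assert z.mean() == pytest.approx(0, abs=1e-9)
        assert z.std() == pytest.approx(1, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            zscale([2.0, 2.0, 2.0], larger_means_selective=False)


class TestMetricAgreement:
    def test_planted_archetypes_rank_consistently(self, synth_default):
        """A planted single-target compound must look more selective than a
        planted 15-target promiscuous compound under every metric."""
        m, truth = synth_default
        scores = score_matrix(m, h=5)
        calls = select_all(m, scores, "local")
        tab = metric_table(m, scores, calls)
        sel = sorted({c for c, _ in truth})[0]     # a planted selective compound
        prom = "C06"                                # first promiscuous compound
        assert tab.loc[sel, "standard_score"] < tab.loc[prom, "standard_score"]
        assert tab.loc[sel, "entropy"] < tab.loc[prom, "entropy"]
        assert tab.loc[sel, "mean_selectivity_score"] > tab.loc[prom, "mean_selectivity_score"]
        assert tab.loc[sel, "n_selective_targets"] <= tab.loc[prom, "n_selective_targets"]
        # partition index at the planted target: concentrated → −log10 near 0
        planted_target = next(t for c, t in truth if c == sel)
        _, neglog_sel = partition_index(m, sel, planted_target)
        worst_prom = min(
            partition_index(m, prom, t)[1] for t in m.targets
        )
        assert neglog_sel < worst_prom
        # harmonized columns: smaller = more selective, for every metric
        zcols = [c for c in tab.columns if c.startswith("z_")]
        assert (tab.loc[sel, zcols] < tab.loc[prom, zcols]).all()

    def test_partition_and_score_negatively_rank_correlated(self, synth_default):
        m, _ = synth_default
        scores = score_matrix(m, h=5).table
        part = partition_index_table(m)
        merged = scores.merge(part, on=["compound", "target"])
        rho = stats.spearmanr(
            merged["neglog10_partition_index"], merged["S"]
        ).statistic
        assert rho < 0
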