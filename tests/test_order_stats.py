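"""Order statistics: tabulation, chi-squared, Fisher 3×2, permutation ranks,
significance tiers, switch points, KS comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fasciq.geometry import BundleProfile, PAIRS
from fasciq.order_stats import (
    MiddlePopulation,
    chi_squared_vs_random,
    compare_switch_points,
    detect_switch_point,
    fisher_exact_3x2,
    majority_profile,
    permutation_rank,
    rank_threshold,
    rank_to_significance,
    simulate_random_counts,
    tabulate_population,
)

from _oracles import fisher_3x2_exact_fraction


def _profile_with_middles(middles, animal_id="a"):
    n = len(middles)
    return BundleProfile(
        animal_id=animal_id,
        bin_d_pairs={tuple(p): np.ones(n) for p in PAIRS},
        bin_width=np.ones(n),
        bin_middle=list(middles),
        bin_ambiguous=np.zeros(n, dtype=bool),
    )


class TestTabulate:
    def test_illustrated_distribution(self):
        """Six animals, five with ASE and one with AFD in the middle at a bin,
        give counts (AWA, AFD, ASE) = (0, 1, 5)."""
        middles = ["ASE"] * 5 + ["AFD"]
        profiles = [_profile_with_middles([m] * 10, f"a{i}") for i, m in enumerate(middles)]
        pop = tabulate_population(profiles)
        np.testing.assert_array_equal(pop.counts[0], [0, 1, 5])

    def test_single_animal_unit_vectors(self):
        pop = tabulate_population([_profile_with_middles(["AWA", "AFD", "ASE"])])
        np.testing.assert_array_equal(pop.counts, np.eye(3, dtype=int)[[0, 1, 2]])

    def test_counts_conserve_animals(self, rng):
        profiles = [
            _profile_with_middles(rng.choice(["AWA", "AFD", "ASE"], size=20), f"a{i}")
            for i in range(7)
        ]
        pop = tabulate_population(profiles)
        assert np.all(pop.counts.sum(axis=1) == 7)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tabulate_population([])

    def test_defasciculated_profiles_rejected(self):
        p = _profile_with_middles(["AFD"] * 5)
        p.defasciculated = True
        with pytest.raises(ValueError, match="excluded"):
            tabulate_population([p])


class TestChiSquared:
    def test_uniform_counts_give_zero(self):
        stat, p = chi_squared_vs_random([7, 7, 7], n=21)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        # (81 + 9 + 36) / 6 for observed (15, 3, 0) against expected 6
        stat, p = chi_squared_vs_random([15, 3, 0])
        assert stat == pytest.approx(21.0)
        assert 0 < p < 1e-4

    def test_small_expected_counts_refused_with_guidance(self):
        with pytest.raises(ValueError, match="permutation"):
            chi_squared_vs_random([10, 2, 2])  # n = 14, expected < 5

    def test_statistic_zero_iff_exactly_uniform(self):
        stat, _ = chi_squared_vs_random([8, 7, 6])
        assert stat > 0


class TestFisher3x2:
    def test_unique_table_given_margins(self):
        assert fisher_exact_3x2([[9, 0, 0], [9, 0, 0]]) == 1.0

    def test_row_swap_symmetry(self):
        assert fisher_exact_3x2([[2, 1, 0], [0, 1, 2]]) == pytest.approx(
            fisher_exact_3x2([[0, 1, 2], [2, 1, 0]])
        )

    @pytest.mark.parametrize(
        "table,expected",
        [
            # reference values computed independently with R's fisher.test
            ([[15, 3, 0], [6, 6, 6]], 0.00315250837087),
            ([[2, 1, 0], [0, 1, 2]], 0.6),
            ([[5, 1, 0], [2, 2, 2]], 0.318181818182),
            ([[10, 5, 3], [4, 9, 5]], 0.164972182839),
            ([[0, 18, 0], [18, 0, 0]], 2.2038238923e-10),
            ([[7, 7, 7], [7, 7, 7]], 1.0),
        ],
    )
    def test_reference_values(self, table, expected):
        assert fisher_exact_3x2(table) == pytest.approx(expected, rel=1e-9)

    @given(st.lists(st.integers(0, 6), min_size=6, max_size=6))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_matches_exact_rational_enumeration(self, cells):
        table = [cells[:3], cells[3:]]
        if sum(cells) == 0:
            return
        assert fisher_exact_3x2(table) == pytest.approx(
            float(fisher_3x2_exact_fraction(table)), rel=1e-10
        )

    @given(st.lists(st.integers(0, 8), min_size=6, max_size=6))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_in_unit_interval_and_column_permutation_invariant(self, cells):
        table = np.array([cells[:3], cells[3:]])
        p = fisher_exact_3x2(table)
        assert 0 < p <= 1.0 + 1e-12
        perm = np.random.default_rng(sum(cells)).permutation(3)
        assert fisher_exact_3x2(table[:, perm]) == pytest.approx(p, rel=1e-9)


class TestSimulateRandomCounts:
    def test_zero_animals(self):
        np.testing.assert_array_equal(simulate_random_counts(0, seed=1), [0, 0, 0])

    def test_seed_reproducibility(self):
        a = simulate_random_counts(18, seed=42)
        b = simulate_random_counts(18, seed=42)
        np.testing.assert_array_equal(a, b)
        assert a.sum() == 18

    def test_mean_is_n_over_three(self):
        rng = np.random.default_rng(7)
        draws = np.array([simulate_random_counts(18, rng) for _ in range(10_000)])
        np.testing.assert_allclose(draws.mean(axis=0), 6.0, atol=0.1)


class TestPermutationRank:
    def test_501_pvalues_total(self):
        res = permutation_rank([15, 3, 0], [6, 6, 6], iterations=500, seed=0)
        assert len(res.resampled_p) == 500 and res.total == 501
        assert 1 <= res.rank <= 501

    def test_identical_populations_rank_maximally(self):
        for seed in range(5):
            res = permutation_rank([6, 6, 6], [6, 6, 6], seed=seed)
            assert res.nominal_p == pytest.approx(1.0)
            assert res.rank == 501

    @pytest.mark.parametrize("seed", range(5))
    def test_fully_separated_cohorts_rank_first(self, seed):
        res = permutation_rank([18, 0, 0], [0, 18, 0], seed=seed)
        assert res.rank == 1 and res.tier == "p<0.01"

    def test_odd_total_splits_unevenly_but_runs(self):
        res = permutation_rank([5, 4, 0], [3, 3, 2], iterations=100, seed=3)
        assert 1 <= res.rank <= 101

    def test_generator_seed_reproducibility(self):
        a = permutation_rank([10, 5, 3], [4, 9, 5], seed=9)
        b = permutation_rank([10, 5, 3], [4, 9, 5], seed=9)
        assert a.rank == b.rank
        np.testing.assert_array_equal(a.resampled_p, b.resampled_p)


class TestRankTiers:
    def test_alpha_thresholds_for_501(self):
        assert rank_threshold(0.05, 501) == 25
        assert rank_threshold(0.01, 501) == 5
        assert rank_threshold(1.0, 501) == 500

    @pytest.mark.parametrize(
        "rank,tier", [(1, "p<0.01"), (5, "p<0.01"), (6, "p<0.05"), (25, "p<0.05"),
                      (26, "ns"), (501, "ns")]
    )
    def test_tier_mapping(self, rank, tier):
        assert rank_to_significance(rank, 501) == tier

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError):
            rank_to_significance(0, 501)


class TestSwitchPoint:
    def test_constant_sequence_has_no_switch(self):
        assert detect_switch_point(["ASE"] * 100) is None

    def test_clean_switch(self):
        sp = detect_switch_point(["AFD"] * 30 + ["ASE"] * 70)
        assert sp.bin_index == 31 and sp.from_label == "AFD" and sp.to_label == "ASE"

    def test_single_bin_blip_is_ignored(self):
        seq = ["AFD"] * 30 + ["ASE"] + ["AFD"] * 5 + ["ASE"] * 64
        sp = detect_switch_point(seq)
        assert sp.bin_index == 37

    def test_majority_profile_ties_resolve_alphabetically(self):
        pop = MiddlePopulation(counts=np.array([[3, 3, 0], [0, 2, 4]]), n_animals=6)
        assert majority_profile(pop) == ["AFD", "ASE"]


class TestCompareSwitchPoints:
    def test_identical_samples(self):
        stat, p = compare_switch_points([30, 35, 40], [30, 35, 40])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        stat, _ = compare_switch_points([1, 2, 3], [10, 11, 12])
        assert stat == 1.0

    def test_matches_hand_ecdf_gap(self):
        a, b = [1.0, 2.0, 4.0], [2.0, 3.0]
        # ECDFs: F_a jumps at 1,2,4 by 1/3; F_b at 2,3 by 1/2; max gap at x∈[3,4): |2/3-1|=...
        # enumerate gaps on pooled points
        pooled = sorted(set(a + b))
        gaps = [
            abs(np.mean(np.asarray(a) <= x) - np.mean(np.asarray(b) <= x)) for x in pooled
        ]
        stat, _ = compare_switch_points(a, b)
        assert stat == pytest.approx(max(gaps))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_switch_points([], [1.0])
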