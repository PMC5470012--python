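"""Agreement statistics against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from par24.concordance import (
    PairedObservation,
    bland_altman,
    icc_two_way_random,
    median_of_differences,
    method_agreement,
    spearman,
    split_strata,
    stratified_comparison,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from par24.errors import ContractError, ValidationError

from oracles import rank_sum_enumeration_p, signed_rank_enumeration_p, spearman_oracle


def pairs_from(a, b, **covariates):
    return [
        PairedObservation(f"P{i:03d}", float(x), float(y), **covariates)
        for i, (x, y) in enumerate(zip(a, b))
    ]


class TestSpearman:
    def test_identity_is_one(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)

    def test_tied_example_matches_rank_then_pearson(self):
        r = spearman([1, 2, 2, 4], [10, 20, 30, 40])
        assert r == pytest.approx(4.5 / np.sqrt(22.5))  # hand-computed midranks
        assert r == pytest.approx(spearman_oracle([1, 2, 2, 4], [10, 20, 30, 40]))

    def test_constant_vector_is_undefined(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman([1.0, 1.0, 1.0], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_oracle_on_random_tied_data(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 31))
        x = rng.integers(0, 8, n).astype(float)
        y = rng.integers(0, 8, n).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            return
        assert spearman(x, y) == pytest.approx(spearman_oracle(list(x), list(y)), abs=1e-12)

    def test_cross_check_against_scipy(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        assert spearman(x, y) == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert spearman(np.exp(x), np.exp(y)) == pytest.approx(spearman(x, y), abs=1e-12)


class TestSignedRank:
    def test_all_zero_differences_are_degenerate(self):
        result = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert result.p_value == 1.0
        assert result.degenerate

    def test_all_positive_small_sample_exact(self):
        # 2^5 sign patterns, W+=15 observed; only W=15 is as extreme each side
        result = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert result.exact
        assert result.p_value == pytest.approx(2 / 32)

    def test_symmetric_tied_pair_gives_p_one(self):
        result = wilcoxon_signed_rank([-1, 1])
        assert result.p_value == 1.0

    @pytest.mark.parametrize("seed", range(40))
    def test_exact_p_matches_sign_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 13))
        diffs = rng.integers(-5, 6, n).astype(float)
        result = wilcoxon_signed_rank(diffs)
        if result.degenerate:
            assert np.all(diffs == 0)
            return
        assert result.exact
        assert result.p_value == signed_rank_enumeration_p(list(diffs))

    def test_normal_approximation_close_to_exact_at_n20(self):
        rng = np.random.default_rng(1)
        diffs = rng.normal(0.3, 1.0, 20)  # continuous, tie-free
        exact = wilcoxon_signed_rank(diffs)
        approx = wilcoxon_signed_rank(diffs, exact_max_n=0)
        assert exact.exact and not approx.exact
        assert approx.p_value == pytest.approx(exact.p_value, abs=0.01)

    def test_cross_check_against_scipy_exact(self):
        diffs = [3.0, -1.0, 4.0, -2.0, 6.0, 5.0, -7.0, 8.0]
        ours = wilcoxon_signed_rank(diffs)
        theirs = stats.wilcoxon(diffs, method="exact", alternative="two-sided")
        assert ours.p_value == pytest.approx(theirs.pvalue)

    def test_pratt_zero_handling_changes_ranks(self):
        diffs = [0.0, 1.0, -2.0, 3.0]
        drop = wilcoxon_signed_rank(diffs, zero_method="drop")
        pratt = wilcoxon_signed_rank(diffs, zero_method="pratt")
        assert drop.statistic != pratt.statistic


class TestRankSum:
    def test_fully_separated_groups_of_three(self):
        # extreme split has probability 2/20 two-sided
        result = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert result.exact
        assert result.p_value == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 2], [1, 2, 2]).p_value == 1.0

    def test_interleaved_groups_match_enumeration(self):
        result = wilcoxon_rank_sum([1, 3, 5], [2, 4, 6])
        assert result.p_value == pytest.approx(0.7)  # 2 * 7/20, hand-enumerated
        assert result.p_value == pytest.approx(rank_sum_enumeration_p([1, 3, 5], [2, 4, 6]))

    @pytest.mark.parametrize("seed", range(40))
    def test_exact_p_matches_split_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_x = int(rng.integers(1, 6))
        n_y = int(rng.integers(1, 6))
        x = rng.integers(0, 6, n_x).astype(float)
        y = rng.integers(0, 6, n_y).astype(float)
        assert wilcoxon_rank_sum(x, y).p_value == pytest.approx(
            rank_sum_enumeration_p(list(x), list(y))
        )

    def test_empty_group_is_a_contract_error(self):
        with pytest.raises(ContractError):
            wilcoxon_rank_sum([], [1.0])

    def test_approximation_cross_check_against_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0.0, 1.0, 30)
        y = rng.normal(0.5, 1.0, 25)
        ours = wilcoxon_rank_sum(x, y)
        theirs = stats.mannwhitneyu(x, y, method="asymptotic", alternative="two-sided")
        assert not ours.exact
        assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-10)


class TestMedianOfDifferences:
    def test_median_of_differences_is_not_difference_of_medians(self):
        pairs = pairs_from([1, 2, 3], [3, 1, 2])
        median_diff, _ = median_of_differences(pairs)
        assert median_diff == 1.0
        a_median = np.median([1, 2, 3])
        b_median = np.median([3, 1, 2])
        assert a_median - b_median == 0.0 != median_diff

    def test_identical_methods_give_zero(self):
        assert median_of_differences(pairs_from([5, 6, 7], [5, 6, 7])) == (0.0, 0.0)

    def test_hand_sorted_median(self):
        pairs = pairs_from([10, 5, 8], [7, 5, 9])  # diffs 3, 0, -1
        median_diff, _ = median_of_differences(pairs)
        assert median_diff == 0.0

    def test_percent_uses_only_positive_denominators(self):
        pairs = pairs_from([10, 10], [0, 5])  # only the second pair has b > 0
        _, pct = median_of_differences(pairs)
        assert pct == pytest.approx(100.0)

    def test_of_medians_rule(self):
        pairs = pairs_from([10, 20, 30], [20, 25, 60])
        median_diff, pct = median_of_differences(pairs, denominator="of_medians")
        assert median_diff == -10.0
        assert pct == pytest.approx(100 * -10 / 25)


class TestBlandAltman:
    def test_identical_inputs(self):
        result = bland_altman(pairs_from([1, 2, 3], [1, 2, 3]))
        assert (result.bias, result.loa_lower, result.loa_upper) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        result = bland_altman(pairs_from([11, 12, 13], [1, 2, 3]))
        assert (result.bias, result.loa_lower, result.loa_upper) == (10.0, 10.0, 10.0)

    def test_sample_sd_limits(self):
        result = bland_altman(pairs_from([0, 2, 4], [2, 2, 2]))  # diffs -2, 0, 2
        assert result.bias == 0.0
        assert result.loa_upper == pytest.approx(1.96 * 2.0)
        assert result.loa_lower == pytest.approx(-1.96 * 2.0)

    def test_single_pair_is_a_contract_error(self):
        with pytest.raises(ContractError):
            bland_altman(pairs_from([1], [2]))

    @pytest.mark.parametrize("seed", range(5))
    def test_swapping_methods_mirrors_everything(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 1000, 20).astype(float)
        b = rng.integers(0, 1000, 20).astype(float)
        forward = bland_altman(pairs_from(a, b))
        backward = bland_altman(pairs_from(b, a))
        assert backward.bias == pytest.approx(-forward.bias)
        assert backward.loa_lower == pytest.approx(-forward.loa_upper)
        assert backward.loa_upper == pytest.approx(-forward.loa_lower)
        assert np.allclose(backward.diffs, -forward.diffs)
        assert np.allclose(backward.means, forward.means)


class TestMethodAgreement:
    def test_perfect_agreement(self):
        result = method_agreement(pairs_from([10, 20, 30], [10, 20, 30]))
        assert result.spearman_r == pytest.approx(1.0)
        assert result.p_method_diff == 1.0
        assert result.degenerate
        assert result.median_diff == 0.0
        assert result.bias == 0.0

    def test_fields_match_component_recomputation(self):
        rng = np.random.default_rng(11)
        a = rng.integers(0, 1440, 25).astype(float)
        b = rng.integers(0, 1440, 25).astype(float)
        pairs = pairs_from(a, b)
        result = method_agreement(pairs, label="light")
        assert result.spearman_r == pytest.approx(spearman(a, b))
        assert result.p_method_diff == wilcoxon_signed_rank(a - b).p_value
        assert (result.median_diff, result.median_pct_diff) == median_of_differences(pairs)
        ba = bland_altman(pairs)
        assert (result.bias, result.loa_lower, result.loa_upper) == (
            ba.bias, ba.loa_lower, ba.loa_upper,
        )

    def test_constant_method_surfaces_undefined_correlation(self):
        with pytest.raises(ValidationError, match="constant"):
            method_agreement(pairs_from([5, 5, 5, 5], [1, 2, 3, 4]))


class TestStratifiedComparison:
    def test_identical_difference_distributions_give_p_one(self):
        pairs = pairs_from([10, 20, 30], [9, 19, 29], age=30) + pairs_from(
            [40, 50, 60], [39, 49, 59], age=70
        )
        comparison = stratified_comparison(pairs, "age")
        assert comparison.between_strata_p == 1.0

    def test_shifted_difference_distributions(self):
        pairs = pairs_from([11, 22, 33], [10, 20, 30], age=30) + pairs_from(
            [20, 31, 42], [10, 20, 30], age=70
        )  # diffs (1, 2, 3) vs (10, 11, 12)
        comparison = stratified_comparison(pairs, "age")
        assert comparison.between_strata_p == pytest.approx(0.1)

    def test_age_cut_is_at_sixty_with_upper_inclusive(self):
        pairs = pairs_from([1, 2], [1, 2])
        pairs = [
            PairedObservation("P59", 1, 1, age=59),
            PairedObservation("P60", 2, 2, age=60),
        ]
        strata = split_strata(pairs, "age")
        assert [p.participant_id for p in strata["age<60"]] == ["P59"]
        assert [p.participant_id for p in strata["age>=60"]] == ["P60"]

    def test_missing_covariates_drop_from_both_strata(self):
        pairs = [PairedObservation("P1", 1, 1, bmi=None), PairedObservation("P2", 2, 2, bmi=30)]
        strata = split_strata(pairs, "bmi")
        assert [p.participant_id for p in strata["bmi>=25"]] == ["P2"]
        assert strata["bmi<25"] == []

    def test_empty_stratum_is_an_error_naming_it(self):
        pairs = pairs_from([1, 2, 3, 4], [2, 3, 4, 5], gender="male")
        with pytest.raises(ValidationError, match="women"):
            stratified_comparison(pairs, "gender")


class TestIcc:
    def test_perfect_agreement_gives_one(self):
        assert icc_two_way_random([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.5, size=30)
        forward = icc_two_way_random(x, y)
        assert -1.0 <= forward <= 1.0
        assert icc_two_way_random(y, x) == pytest.approx(forward)
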