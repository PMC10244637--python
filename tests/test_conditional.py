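import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insightbench import (
    CombinationCapError,
    build_conditional,
    enumerate_conditional,
    enumerate_conditional_mitm,
    percentile_rank,
    placement,
    profile_probability,
    score_pmf_dp,
    top_fraction_threshold,
)
from tests.conftest import random_rates

mid_rates = st.lists(
    st.floats(min_value=0.02, max_value=0.98), min_size=2, max_size=12
)


class TestProfileProbability:
    def test_practice_probability(self, practice_battery, practice_profile):
        p = profile_probability(practice_battery, practice_profile)
        assert p == pytest.approx(1.52e-04, rel=5e-3)

    def test_transfer_probability(self, transfer_battery, transfer_profile):
        p = profile_probability(transfer_battery, transfer_profile)
        assert p == pytest.approx(5.01e-05, rel=5e-3)

    def test_pooled_factorizes(self, pooled_battery, pooled_profile,
                               practice_battery, practice_profile,
                               transfer_battery, transfer_profile):
        pooled = profile_probability(pooled_battery, pooled_profile)
        parts = profile_probability(practice_battery, practice_profile) * (
            profile_probability(transfer_battery, transfer_profile)
        )
        assert pooled == pytest.approx(7.61e-09, rel=5e-3)
        assert pooled == pytest.approx(parts, rel=1e-14)

    def test_trivial_two_items(self):
        assert profile_probability([0.5, 0.5], [1, 0]) == pytest.approx(0.25)

    def test_length_mismatch(self, practice_battery):
        with pytest.raises(ValueError, match="length"):
            profile_probability(practice_battery, [1, 0, 1])

    def test_degenerate_rates(self):
        assert profile_probability([1.0, 0.0], [1, 0]) == 1.0
        assert profile_probability([1.0, 0.0], [0, 1]) == 0.0


class TestDirectEnumeration:
    def test_practice_level_set_size(self, practice_battery):
        dist = enumerate_conditional(practice_battery, 7)
        assert dist.m == math.comb(15, 7) == 6435
        assert dist.probabilities.size == 6435

    def test_conservation_against_pmf(self, practice_battery):
        dist = enumerate_conditional(practice_battery, 7)
        assert dist.sum() == pytest.approx(score_pmf_dp(practice_battery)[7], rel=1e-10)

    def test_exchangeable_probabilities_all_equal(self):
        dist = enumerate_conditional([0.5] * 10, 4)
        assert np.allclose(dist.probabilities, 0.5**10)

    def test_cap_advises_mitm(self, pooled_battery):
        with pytest.raises(CombinationCapError, match="mitm"):
            enumerate_conditional(pooled_battery, 12, cap=10**6)

    def test_zero_rate_combinations_still_counted(self):
        dist = enumerate_conditional([0.0, 0.5, 0.5], 2)
        assert dist.m == 3
        assert np.count_nonzero(dist.probabilities == 0.0) == 2

    @settings(max_examples=50, deadline=None)
    @given(rates=mid_rates, data=st.data())
    def test_conservation_property(self, rates, data):
        k = data.draw(st.integers(min_value=0, max_value=len(rates)))
        dist = enumerate_conditional(rates, k)
        assert dist.sum() == pytest.approx(score_pmf_dp(rates)[k], rel=1e-10)


class TestMitm:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 17))
        rates = random_rates(rng, n)
        k = int(rng.integers(0, n + 1))
        direct = np.sort(enumerate_conditional(rates, k).probabilities)
        mitm = enumerate_conditional_mitm(rates, k, chunk_size=64)
        streamed = np.sort(np.concatenate(list(mitm.iter_chunks())))
        assert mitm.m == direct.size
        assert np.allclose(streamed, direct, rtol=1e-12)

    def test_pooled_combination_count_exceeds_printed_bound(self, pooled_battery):
        dist = enumerate_conditional_mitm(pooled_battery, 12)
        assert dist.m == math.comb(30, 12) == 86_493_225
        assert dist.m > 86_000_000

    def test_pooled_conservation(self, pooled_battery):
        dist = enumerate_conditional_mitm(pooled_battery, 12)
        assert dist.sum() == pytest.approx(score_pmf_dp(pooled_battery)[12], rel=1e-10)

    def test_uniform_rates_all_equal(self):
        dist = enumerate_conditional_mitm([0.5] * 30, 12)
        assert dist.min() == pytest.approx(0.5**30, rel=1e-12)
        assert dist.max() == pytest.approx(0.5**30, rel=1e-12)

    def test_chunk_size_validation(self):
        with pytest.raises(ValueError, match="chunk_size"):
            enumerate_conditional_mitm([0.5] * 4, 2, chunk_size=0)

    def test_count_and_rank_agree_with_dense(self):
        rng = np.random.default_rng(7)
        rates = random_rates(rng, 14)
        direct = enumerate_conditional(rates, 6)
        mitm = enumerate_conditional_mitm(rates, 6, chunk_size=128)
        ascending = np.sort(direct.probabilities)
        for rank in (1, 2, 100, 2000, direct.m):
            assert mitm.nth_smallest(rank) == pytest.approx(ascending[rank - 1], rel=1e-12)
        # counts compared at tie-offset thresholds: the two backends compute
        # probabilities along different float paths, so raw element
        # boundaries can differ in the last ulp
        for t in (ascending[0], ascending[direct.m // 2], ascending[-1] * 2):
            assert mitm.count_less(t * (1 - 1e-9)) == direct.count_less(t * (1 - 1e-9))
            assert mitm.count_less(t * (1 + 1e-9)) == direct.count_less(t * (1 + 1e-9))
        p = ascending[direct.m // 3]
        assert percentile_rank(mitm, p) == percentile_rank(direct, p)

    def test_bisection_rank_path(self):
        rng = np.random.default_rng(11)
        rates = random_rates(rng, 12)
        direct = enumerate_conditional(rates, 5)
        mitm = enumerate_conditional_mitm(rates, 5, chunk_size=16)
        # chunk_size 16 forces the bisection path for mid ranks
        mid = direct.m // 2
        assert mitm.nth_smallest(mid) == pytest.approx(
            np.sort(direct.probabilities)[mid - 1], rel=1e-12
        )


class TestPercentileAndThreshold:
    def test_below_everything_is_zero(self, practice_battery):
        dist = enumerate_conditional(practice_battery, 7)
        assert percentile_rank(dist, dist.min() / 10) == 0.0

    def test_transfer_profile_percentile(self, transfer_battery, transfer_profile):
        dist = enumerate_conditional(transfer_battery, 5)
        p = profile_probability(transfer_battery, transfer_profile)
        pct = percentile_rank(dist, p)
        assert pct == pytest.approx(26.14, abs=0.01)
        assert abs(pct - 27.0) < 1.5  # printed as "neared the 27th percentile"

    def test_all_equal_distribution_ties_rank_zero(self):
        dist = enumerate_conditional([0.5] * 8, 3)
        assert percentile_rank(dist, 0.5**8) == 0.0
        assert top_fraction_threshold(dist, 0.05) == pytest.approx(0.5**8)

    def test_practice_threshold(self, practice_battery):
        dist = enumerate_conditional(practice_battery, 7)
        threshold = top_fraction_threshold(dist, 0.05)
        assert threshold == pytest.approx(1.50e-04, rel=5e-3)

    def test_threshold_monotone_in_q(self, transfer_battery):
        dist = enumerate_conditional(transfer_battery, 5)
        qs = [0.01, 0.05, 0.1, 0.25, 0.5, 0.9]
        thresholds = [top_fraction_threshold(dist, q) for q in qs]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_q_bounds(self, transfer_battery):
        dist = enumerate_conditional(transfer_battery, 5)
        for q in (0.0, 1.0, -0.1, 1.1):
            with pytest.raises(ValueError):
                top_fraction_threshold(dist, q)


class TestPlacement:
    def test_practice_in_top_q(self, practice_battery, practice_profile):
        report = placement(practice_battery, practice_profile, q=0.05)
        assert report.in_top_q
        assert report.method == "direct"
        assert report.k == 7 and report.m == 6435

    def test_transfer_not_in_top_q(self, transfer_battery, transfer_profile):
        report = placement(transfer_battery, transfer_profile, q=0.05)
        assert not report.in_top_q

    def test_pooled_in_top_q_via_mitm(self, pooled_battery, pooled_profile):
        report = placement(pooled_battery, pooled_profile, q=0.05)
        assert report.in_top_q
        assert report.method == "mitm"
        assert report.m == 86_493_225
        assert report.top_q_threshold == pytest.approx(7.35e-09, rel=2e-3)

    def test_membership_consistent_with_threshold(self, transfer_battery, transfer_profile):
        report = placement(transfer_battery, transfer_profile, q=0.05)
        assert report.in_top_q == (
            report.profile_probability >= report.top_q_threshold * (1 - 1e-9)
        )

    def test_exchangeable_everyone_in_top_q(self):
        report = placement([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0], q=0.05)
        assert report.percentile_rank == 0.0
        assert report.in_top_q

    def test_auto_selects_mitm_under_small_cap(self, practice_battery, practice_profile):
        report = placement(practice_battery, practice_profile, q=0.05, direct_cap=100)
        assert report.method == "mitm"
        direct = placement(practice_battery, practice_profile, q=0.05)
        assert report.top_q_threshold == pytest.approx(direct.top_q_threshold, rel=1e-12)
        assert report.percentile_rank == pytest.approx(direct.percentile_rank)
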