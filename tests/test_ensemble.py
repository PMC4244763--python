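import numpy as np
import pytest
from scipy import stats as sps

from conftest import random_binary
from oracles import mann_whitney_exact_oracle

from nestkit import (
    compute_stats,
    make_fixture,
    mann_whitney_u,
    normalised_temperature,
    run_adaptive_ensemble,
    run_fixed_ensemble,
    z_score,
)
from nestkit.measures import Direction


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        assert mann_whitney_u([1, 2], [3, 4]) == pytest.approx(1.0 / 3.0)
        assert mann_whitney_exact_oracle([1, 2], [3, 4]) == pytest.approx(1.0 / 3.0)

    def test_identical_constant_samples_give_p_one(self):
        assert mann_whitney_u([2.0, 2.0, 2.0], [2.0, 2.0]) == 1.0

    def test_identical_arrays_give_p_one(self):
        x = np.array([1.0, 5.0, 5.0, 9.0])
        assert mann_whitney_u(x, x) == 1.0

    def test_matches_exact_oracle_on_small_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.permutation(20)[:4].astype(float)
            y = rng.permutation(40)[:5].astype(float) + 0.5
            assert mann_whitney_u(x, y) == pytest.approx(
                mann_whitney_exact_oracle(x, y), abs=1e-12
            )

    def test_p_uniform_under_null(self):
        """Over replicated same-distribution samples of size 500, the U-test
        p-value is uniform on (0,1) (KS test at the 1% level)."""
        rng = np.random.default_rng(1)
        ps = [
            mann_whitney_u(rng.normal(size=500), rng.normal(size=500))
            for _ in range(1_000)
        ]
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestComputeStats:
    def test_hand_enumerated_four_member_ensemble(self):
        s = compute_stats(5.0, [1.0, 2.0, 3.0, 4.0], Direction.HIGHER_IS_MORE_NESTED)
        assert s.p == 0.25 and s.p_is_bound
        assert s.mean == 2.5
        assert s.T == pytest.approx(2.0)
        assert s.sd == pytest.approx(np.std([1, 2, 3, 4], ddof=1))

    def test_direction_flips_the_counted_tail(self):
        ens = [1.0, 2.0, 3.0, 4.0]
        lower = compute_stats(2.5, ens, Direction.LOWER_IS_MORE_NESTED)
        higher = compute_stats(2.5, ens, Direction.HIGHER_IS_MORE_NESTED)
        assert lower.p == 0.5  # members 1, 2 are more nested
        assert higher.p == 0.5  # members 3, 4 are more nested

    def test_ties_count_as_not_more_nested(self):
        s = compute_stats(3.0, [3.0, 3.0, 4.0, 1.0], Direction.HIGHER_IS_MORE_NESTED)
        assert s.p == 0.25 and not s.p_is_bound

    def test_published_worked_example_identities(self):
        """z and T recomputed from the case study's printed inputs."""
        assert z_score(44.4339, 29.9048, 3.5600) == pytest.approx(4.0812, abs=5e-5)
        assert normalised_temperature(44.4339, 45.3207) == pytest.approx(0.9804, abs=2e-4)
        assert normalised_temperature(44.4339, 29.9048) == pytest.approx(1.4858, abs=2e-4)
        # the printed mean/sd are rounded, so the 4th decimal can shift by one
        assert z_score(44.4339, 45.3207, 0.8357) == pytest.approx(-1.0612, abs=2e-4)

    def test_identities_hold_to_machine_precision(self):
        rng = np.random.default_rng(2)
        ens = rng.normal(50, 5, size=1000)
        s = compute_stats(60.0, ens, Direction.HIGHER_IS_MORE_NESTED)
        assert abs(s.T - s.observed / s.mean) < 1e-12
        assert abs(s.z - (s.observed - s.mean) / s.sd) < 1e-12
        assert (s.p * s.N) == pytest.approx(round(s.p * s.N), abs=1e-9)
        assert 1 / s.N <= s.p <= 1

    def test_degenerate_ensembles_warn_and_report_missing(self):
        with pytest.warns(UserWarning):
            s = compute_stats(1.0, [2.0, 2.0, 2.0], Direction.HIGHER_IS_MORE_NESTED)
        assert s.z is None
        with pytest.warns(UserWarning):
            s = compute_stats(1.0, [0.0, 0.0], Direction.HIGHER_IS_MORE_NESTED)
        assert s.T is None


class TestFixedEnsemble:
    def test_scores_have_requested_size_and_range(self, triangle3):
        res = run_fixed_ensemble(triangle3, "SS", ("NODF",), 10, np.random.default_rng(0))
        assert res.N == 10 and len(res.scores["NODF"]) == 10
        assert np.all((res.scores["NODF"] >= 0) & (res.scores["NODF"] <= 100))

    def test_all_measures_share_the_same_draws(self):
        m = random_binary(6, 6, 15, 1)
        r1 = run_fixed_ensemble(m, "FF", ("NODF", "SR"), 50, np.random.default_rng(3))
        r2 = run_fixed_ensemble(m, "FF", ("NODF",), 50, np.random.default_rng(3))
        assert np.array_equal(r1.scores["NODF"], r2.scores["NODF"])

    def test_same_seed_is_deterministic(self):
        m = random_binary(6, 6, 15, 2)
        a = run_fixed_ensemble(m, "CC", ("NODF", "MD"), 100, np.random.default_rng(9))
        b = run_fixed_ensemble(m, "CC", ("NODF", "MD"), 100, np.random.default_rng(9))
        assert np.array_equal(a.scores["NODF"], b.scores["NODF"])
        assert np.array_equal(a.scores["MD"], b.scores["MD"])

    def test_empty_collapses_are_redrawn(self):
        # 2x2 with fill 1: EE draws frequently collapse to all-zero
        m = random_binary(2, 2, 1, 3)
        res = run_fixed_ensemble(m, "EE", ("SR",), 200, np.random.default_rng(4))
        assert res.N == 200
        assert res.redraws > 0


class TestAdaptiveEnsemble:
    def test_growth_arithmetic_and_bounds(self):
        m = random_binary(6, 6, 15, 5)
        res = run_adaptive_ensemble(m, "SS", ("NODF",), np.random.default_rng(6))
        assert res.adaptive
        assert 1_000 <= res.N <= 100_000
        assert res.N % 1_000 == 0

    def test_same_null_groups_usually_merge_immediately(self):
        m = random_binary(6, 6, 15, 7)
        sizes = [
            run_adaptive_ensemble(m, "SS", ("NODF",), np.random.default_rng(seed)).N
            for seed in range(10)
        ]
        assert all(n >= 1_000 for n in sizes)
        # the first U-test accepts with probability 0.9
        assert sizes.count(1_000) >= 7

    def test_fixed_and_adaptive_paths_agree_in_distribution(self):
        """Means from fixed-size and adaptive ensembles of the same null are
        statistically indistinguishable (two-sample t-test at the 1% level)."""
        m = random_binary(5, 5, 11, 8)
        fixed_means, adaptive_means = [], []
        for seed in range(50):
            f = run_fixed_ensemble(m, "SS", ("NODF",), 200, np.random.default_rng([seed, 0]))
            a = run_adaptive_ensemble(m, "SS", ("NODF",), np.random.default_rng([seed, 1]))
            fixed_means.append(f.scores["NODF"].mean())
            adaptive_means.append(a.scores["NODF"].mean())
        assert sps.ttest_ind(fixed_means, adaptive_means).pvalue > 0.01
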