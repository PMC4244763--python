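import numpy as np
import pytest

from conftest import random_binary, random_weighted
from oracles import (
    br_oracle,
    jdm_oracle,
    md_oracle,
    nodf_oracle,
    temperature_oracle,
    wnodf_oracle,
)

import nestkit as nk
from nestkit import BipartiteMatrix
from nestkit.measures import ALL_MEASURES, Direction
from nestkit.sorting import degree_sort


class TestNODF:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([[1, 1, 1], [1, 1, 0], [1, 0, 0]], 100.0),
            ([[1, 0], [0, 1]], 0.0),
            ([[1, 1, 1], [1, 1, 1], [1, 0, 0]], 400.0 / 6.0),
        ],
    )
    def test_frozen_examples(self, values, expected):
        assert nk.nodf(BipartiteMatrix(np.array(values, dtype=float))) == pytest.approx(expected)

    def test_rejects_weighted_input(self):
        with pytest.raises(ValueError, match="binary"):
            nk.nodf(BipartiteMatrix(np.array([[2.0, 1], [1, 0]])))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        m = degree_sort(random_binary(6, 7, 17, seed)).matrix
        assert nk.nodf(m) == pytest.approx(nodf_oracle(m.values), abs=1e-12)


class TestWNODF:
    def test_binary_input_scores_zero(self):
        m = random_binary(5, 5, 12, 3)
        assert nk.wnodf(m) == 0.0

    def test_perfect_weighted_staircase_scores_100(self):
        nested, _ = nk.direction_fixtures()
        assert nk.wnodf(degree_sort(nested).matrix) == pytest.approx(100.0)

    def test_single_pair_example(self):
        assert nk.wnodf(BipartiteMatrix(np.array([[2.0, 1], [1, 0]]))) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = degree_sort(random_weighted(5, 6, 14, seed)).matrix
        assert nk.wnodf(m) == pytest.approx(wnodf_oracle(m.values), abs=1e-12)


class TestManhattanDistance:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([[1]], 0.0),
            ([[1, 0], [0, 1]], 2.0),
            ([[1, 1, 1], [1, 1, 0], [1, 0, 0]], 8.0),
        ],
    )
    def test_frozen_examples(self, values, expected):
        assert nk.manhattan_distance(BipartiteMatrix(np.array(values, dtype=float))) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = random_binary(5, 8, 15, seed)
        assert nk.manhattan_distance(m) == md_oracle(m.values)


class TestTemperature:
    def test_perfect_triangle_is_cold(self):
        assert nk.temperature(nk.make_fixture("nested", 10, 10, 55)) == pytest.approx(0.0, abs=1e-6)

    def test_full_matrix_is_cold(self):
        assert nk.temperature(BipartiteMatrix(np.ones((5, 5)))) == 0.0

    def test_rejects_degenerate_matrix(self):
        with pytest.raises(ValueError):
            nk.temperature(BipartiteMatrix(np.array([[1.0, 0]])))

    def test_single_unexpected_presence_matches_geometric_oracle(self):
        # nearly nested 5x5 with one isolated extra presence in the corner
        values = np.array(
            [
                [1, 1, 1, 1, 0],
                [1, 1, 1, 0, 0],
                [1, 1, 0, 0, 0],
                [1, 0, 0, 0, 0],
                [0, 0, 0, 0, 1],
            ],
            dtype=float,
        )
        got = nk.temperature(BipartiteMatrix(values), sort=False)
        assert got == pytest.approx(temperature_oracle(values), rel=1e-5)

    @pytest.mark.parametrize("seed", range(10))
    def test_unsorted_temperature_matches_oracle(self, seed):
        m = random_binary(5, 6, 13, seed)
        got = nk.temperature(m, sort=False)
        assert got == pytest.approx(temperature_oracle(m.values), rel=1e-5, abs=1e-8)


class TestJDM:
    def test_complete_matrix_scores_one(self):
        assert nk.jdm(BipartiteMatrix(np.ones((4, 3)))) == pytest.approx(1.0)

    def test_identity_scores_zero(self):
        assert nk.jdm(BipartiteMatrix(np.eye(2))) == 0.0

    def test_triangle_frozen_from_oracle(self):
        tri = BipartiteMatrix(np.array([[1.0, 1, 1], [1, 1, 0], [1, 0, 0]]))
        assert nk.jdm(tri) == pytest.approx(12.0 / 11.0)
        assert jdm_oracle(tri.values) == pytest.approx(12.0 / 11.0)

    def test_rejects_1x1(self):
        with pytest.raises(ValueError):
            nk.jdm(BipartiteMatrix(np.array([[1.0]])))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = random_binary(6, 5, 14, seed)
        assert nk.jdm(m) == pytest.approx(jdm_oracle(m.values), abs=1e-12)


class TestDiscrepancy:
    def test_packed_matrix_scores_zero(self):
        assert nk.discrepancy(nk.make_fixture("nested", 5, 5, 12)) == 0

    @pytest.mark.parametrize(
        "values, expected",
        [
            ([[1, 0, 1], [1, 1, 0]], 1),
            ([[1, 0], [0, 1]], 1),
        ],
    )
    def test_frozen_examples(self, values, expected):
        assert nk.discrepancy(BipartiteMatrix(np.array(values, dtype=float))) == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce(self, seed):
        m = degree_sort(random_binary(6, 6, 15, seed)).matrix
        assert nk.discrepancy(m) == br_oracle(m.values)


class TestSpectralRadius:
    def test_singleton(self):
        assert nk.spectral_radius(BipartiteMatrix(np.array([[1.0]]))) == pytest.approx(1.0)

    def test_all_ones_2x2(self):
        assert nk.spectral_radius(BipartiteMatrix(np.ones((2, 2)))) == pytest.approx(2.0)

    def test_equals_embedding_eigenvalue(self):
        m = random_weighted(4, 5, 11, 9)
        B = m.values
        A = np.block([[np.zeros((4, 4)), B], [B.T, np.zeros((5, 5))]])
        assert nk.spectral_radius(m) == pytest.approx(np.linalg.eigvalsh(A).max(), abs=1e-9)

    def test_maximal_over_fixed_fill_is_attained_by_nested_matrix(self):
        """Exhaustively over 4x4 binary matrices with fill 8, the largest
        spectral radius belongs to a matrix whose sorted form is perfectly
        nested (row supports form a subset chain)."""
        from itertools import combinations

        best_sr, best = -1.0, None
        for cells in combinations(range(16), 8):
            B = np.zeros(16)
            B[list(cells)] = 1.0
            sr = np.linalg.svd(B.reshape(4, 4), compute_uv=False)[0]
            if sr > best_sr:
                best_sr, best = sr, B.reshape(4, 4)
        sorted_best = degree_sort(BipartiteMatrix(best)).matrix.values != 0
        for i in range(3):
            assert np.all(sorted_best[i] | ~sorted_best[i + 1])  # next row is a subset


class TestDirections:
    def test_fixture_constraints(self):
        nested, checker = nk.direction_fixtures()
        for fixture in (nested, checker):
            assert fixture.fill == 55
            assert fixture.values.sum() == 220.0

    @pytest.mark.parametrize(
        "measure, expected",
        [
            ("NODF", Direction.HIGHER_IS_MORE_NESTED),
            ("JDM", Direction.HIGHER_IS_MORE_NESTED),
            ("SR", Direction.HIGHER_IS_MORE_NESTED),
            ("WNODF", Direction.HIGHER_IS_MORE_NESTED),
            ("MD", Direction.LOWER_IS_MORE_NESTED),
            ("NTC", Direction.LOWER_IS_MORE_NESTED),
            ("BR", Direction.LOWER_IS_MORE_NESTED),
        ],
    )
    def test_detected_directions(self, measure, expected):
        assert nk.detect_direction(measure) is expected

    def test_unknown_measure_rejected(self):
        with pytest.raises(ValueError):
            nk.detect_direction("BOGUS")

    def test_measure_score_bundles_value_and_direction(self, triangle3):
        s = nk.measure_score(triangle3, "NODF")
        assert s.value == pytest.approx(100.0)
        assert s.direction is Direction.HIGHER_IS_MORE_NESTED
        assert s.measure_id == "NODF"


class TestRangesAndInvariance:
    def test_score_ranges_on_random_fixtures(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n, m = rng.integers(3, 8, size=2)
            fill = int(rng.integers(max(n, m), n * m + 1))
            mat = random_binary(n, m, fill, int(rng.integers(1 << 30)))
            scores = nk.score_matrix(mat, ALL_MEASURES)
            assert 0.0 <= scores["NODF"] <= 100.0
            assert 0.0 <= scores["WNODF"] <= 100.0
            assert 0.0 <= scores["NTC"] <= 100.0
            assert scores["MD"] >= 0 and float(scores["MD"]).is_integer()
            assert scores["BR"] >= 0 and float(scores["BR"]).is_integer()
            assert scores["SR"] >= 0.0
            assert scores["JDM"] >= 0.0

    def test_jdm_and_sr_are_order_invariant(self):
        m = random_binary(6, 7, 18, 21)
        rng = np.random.default_rng(5)
        jdm0, sr0 = nk.jdm(m), nk.spectral_radius(m)
        for _ in range(25):
            p = m.permuted(rng.permutation(6), rng.permutation(7))
            assert nk.jdm(p) == pytest.approx(jdm0, abs=1e-9)
            assert nk.spectral_radius(p) == pytest.approx(sr0, abs=1e-9)
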