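import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retica import (cartesian_grid, occupancy_histogram, kld_to_uniform,
                    null_kld_distribution, uniformity_test, gen_point_set,
                    PointSet, OUTCOME_REGULAR)
from retica.uniformity import HistogramGrid


class TestCartesianGrid:
    @pytest.mark.parametrize("M,n1,n2", [(100, 10, 10), (142, 12, 12),
                                         (4, 2, 2), (20, 4, 5)])
    def test_best_integer_approximation(self, M, n1, n2):
        ps, N1, N2 = cartesian_grid(M, 1.0)
        assert (N1, N2) == (n1, n2)
        assert ps.M == N1 * N2

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            cartesian_grid(3, 1.0)


class TestOccupancyHistogram:
    def test_grid_through_own_tiling_is_flat(self):
        ps, N1, N2 = cartesian_grid(100, 2.0)
        h = occupancy_histogram(ps, N1, N2)
        assert np.all(h.counts == 1)

    def test_counts_conserve_points(self):
        ps = gen_point_set("uniform", 137, 1.0, seed=1)
        h = occupancy_histogram(ps, 11, 12)
        assert h.M == 137

    def test_hand_placed_points(self):
        ps = PointSet(np.array([[0.1, 0.1], [0.9, 0.1], [0.9, 0.9]]), 1.0)
        h = occupancy_histogram(ps, 2, 2)
        np.testing.assert_array_equal(h.counts, [[1, 1], [0, 1]])

    def test_upper_boundary_goes_to_last_bin(self):
        ps = PointSet(np.array([[1.0, 1.0]]), 1.0)
        h = occupancy_histogram(ps, 2, 2)
        assert h.counts[1, 1] == 1

    def test_out_of_domain_rejected(self):
        ps = PointSet(np.array([[0.5, 0.5]]), 1.0)
        ps.points = np.array([[0.5, 2.0]])   # bypass constructor check
        with pytest.raises(ValueError):
            occupancy_histogram(ps, 2, 2)


class TestKld:
    def test_flat_histogram_attains_lower_bound(self):
        ps, N1, N2 = cartesian_grid(100, 1.0)
        assert kld_to_uniform(occupancy_histogram(ps, N1, N2)) == 0.0

    def test_hand_computed_value(self):
        h = HistogramGrid(np.array([[2, 1, 1]]), 1.0)
        assert kld_to_uniform(h) == pytest.approx(0.058892, abs=1e-6)

    def test_bits_conversion(self):
        h = HistogramGrid(np.array([[2, 1, 1]]), 1.0)
        assert kld_to_uniform(h, bits=True) == pytest.approx(
            kld_to_uniform(h) / np.log(2))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 20), min_size=2, max_size=30)
           .filter(lambda c: sum(c) > 0))
    def test_entropy_identity(self, counts):
        h = HistogramGrid(np.array([counts]), 1.0)
        p = np.array(counts) / sum(counts)
        nz = p > 0
        entropy = -np.sum(p[nz] * np.log(p[nz]))
        assert kld_to_uniform(h) == pytest.approx(np.log(len(counts)) - entropy,
                                                  abs=1e-12)

    def test_invariant_under_bin_relabeling(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 10, 24)
        a = HistogramGrid(counts.reshape(4, 6), 1.0)
        b = HistogramGrid(rng.permutation(counts).reshape(6, 4), 1.0)
        assert kld_to_uniform(a) == pytest.approx(kld_to_uniform(b))


class TestNullDistribution:
    def test_nonnegative_and_reproducible(self):
        a = null_kld_distribution(50, 1.0, 7, 7, n_real=500, seed=3)
        b = null_kld_distribution(50, 1.0, 7, 7, n_real=500, seed=3)
        assert np.all(a.sample >= 0)
        np.testing.assert_array_equal(a.sample, b.sample)

    def test_domain_scale_invariance(self):
        a = null_kld_distribution(64, 1.0, 8, 8, n_real=500, seed=5)
        b = null_kld_distribution(64, 7.3, 8, 8, n_real=500, seed=5)
        np.testing.assert_array_equal(a.sample, b.sample)

    def test_against_multinomial_oracle(self):
        # uniform binning makes counts multinomial(M, 1/B): an independent
        # second implementation of the same null
        M, N1, N2 = 4, 2, 2
        null = null_kld_distribution(M, 1.0, N1, N2, n_real=10000, seed=7)
        rng = np.random.default_rng(8)
        counts = rng.multinomial(M, np.full(4, 0.25), size=10000)
        p = counts / M
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, p * np.log(p), 0.0)
        oracle = np.log(4) + terms.sum(axis=1)
        sem = np.hypot(null.sem, oracle.std(ddof=1) / 100)
        assert abs(null.mu - oracle.mean()) < 3 * sem

    def test_too_few_realizations_rejected(self):
        with pytest.raises(ValueError):
            null_kld_distribution(10, 1.0, 3, 3, n_real=50)


class TestUniformityTest:
    def test_cartesian_grid_is_more_regular(self):
        ps, _, _ = cartesian_grid(100, 1.0)
        res = uniformity_test(ps, n_real=1000, seed=1)
        assert res.kld_obs == 0.0
        assert res.outcome == OUTCOME_REGULAR

    def test_result_invariants(self):
        ps = gen_point_set("uniform", 80, 1.0, seed=2)
        res = uniformity_test(ps, n_real=1000, seed=3)
        assert 0 < res.p_left <= 1
        assert res.ci[0] <= res.null_mean <= res.ci[1]
        assert res.ci == pytest.approx(
            (res.null_mean - 2.576 * res.null_sem,
             res.null_mean + 2.576 * res.null_sem))
        assert res.M == 80 and res.N1 * res.N2 >= 4

    def test_json_report_fields(self):
        ps = gen_point_set("uniform", 50, 1.0, seed=4)
        d = uniformity_test(ps, n_real=500, seed=5).to_dict()
        for key in ("M", "N1", "N2", "kld_obs", "p_left", "mu", "sem",
                    "ci", "outcome"):
            assert key in d
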