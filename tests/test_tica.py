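import numpy as np
import pytest

from retica import (build_topology, tica_objective, fit_tica, receptive_fields,
                    amari_index, NonlinearitySpec, TopographicICA,
                    gen_ica_patches, whiten, PatchDataset)
from retica.tica import Topology


class TestTopology:
    def test_row_sums_equal_window_area(self):
        t = build_topology(20, 20, 5)
        assert np.all(t.H.sum(axis=1) == 25)
        assert np.all(t.H.sum(axis=0) == 25)

    def test_symmetric_with_unit_diagonal(self):
        t = build_topology(8, 6, 3)
        np.testing.assert_array_equal(t.H, t.H.T)
        assert np.all(np.diag(t.H) == 1)

    def test_identity_for_single_cell_window(self):
        t = build_topology(5, 5, 1)
        np.testing.assert_array_equal(t.H, np.eye(25))

    def test_toroidal_wraparound_at_corner(self):
        n1 = n2 = 10
        t = build_topology(n1, n2, 5)
        window = set(t.window_indices(0, 0))
        assert (n1 - 2) * n2 + (n2 - 2) in window      # unit (n1-2, n2-2)
        # oracle: enumerate the window indices modulo the torus dims
        expect = {(r % n1) * n2 + (c % n2)
                  for r in range(-2, 3) for c in range(-2, 3)}
        assert window == expect
        np.testing.assert_array_equal(np.flatnonzero(t.H[0]),
                                      np.sort(list(expect)))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            build_topology(10, 10, 4)


class TestObjective:
    def test_rotation_invariance_complete_case(self):
        # p=1, eps=0, H=I: objective is minus the mean squared norm,
        # identical for every orthonormal W
        rng = np.random.default_rng(0)
        Z = rng.standard_normal((200, 9))
        topo = build_topology(3, 3, 1)
        nl = NonlinearitySpec("power", 1.0, 0.0)
        expect = -np.mean(np.sum(Z ** 2, axis=1))
        for seed in range(3):
            W, _ = np.linalg.qr(np.random.default_rng(seed)
                                .standard_normal((9, 9)))
            assert tica_objective(W, Z, topo, nl) == pytest.approx(expect)

    def test_two_unit_toy_value(self):
        topo = Topology(1, 2, 1, np.ones((2, 2)))
        val = tica_objective(np.eye(2), np.array([[1.0, 0.0]]), topo,
                             NonlinearitySpec("power", 0.5, 0.0))
        assert val == pytest.approx(-2.0)

    @pytest.mark.parametrize("p", [0.2, 0.5, 0.8])
    def test_homogeneity_in_input_scale(self, p):
        rng = np.random.default_rng(1)
        Z = rng.standard_normal((50, 16))
        W, _ = np.linalg.qr(rng.standard_normal((16, 16)))
        topo = build_topology(4, 4, 3)
        nl = NonlinearitySpec("power", p, 0.0)
        c = 1.7
        assert tica_objective(W, c * Z, topo, nl) == pytest.approx(
            c ** (2 * p) * tica_objective(W, Z, topo, nl))

    def test_nonfinite_rejected(self):
        topo = build_topology(2, 2, 1)
        with pytest.raises(ValueError):
            tica_objective(np.eye(4), np.full((3, 4), np.nan), topo,
                           NonlinearitySpec())


class TestFit:
    def test_orthonormality_and_determinism(self, whitened_patches):
        _, Z, _ = whitened_patches
        topo = build_topology(6, 6, 3)
        m1 = fit_tica(Z, topo, n_iter=30, seed=4)
        m2 = fit_tica(Z, topo, n_iter=30, seed=4)
        assert np.max(np.abs(m1.W @ m1.W.T - np.eye(36))) < 1e-8
        np.testing.assert_array_equal(m1.W, m2.W)
        assert len(m1.objective_trace) == m1.n_iter + 1

    def test_trace_monotone_nondecreasing(self, whitened_patches):
        _, Z, _ = whitened_patches
        model = fit_tica(Z, build_topology(6, 6, 3), n_iter=50, seed=1)
        assert np.all(np.diff(model.objective_trace) >= -1e-9)

    def test_plain_ica_recovery(self):
        # H = I reduces training to sparse ICA; the Amari index between the
        # estimated unmixing and the true mixing is the recovery oracle
        X, A = gen_ica_patches(9, 9000, seed=11)
        Z, wm = whiten(PatchDataset(X, 3, 1.0), 9)
        model = fit_tica(Z, build_topology(3, 3, 1), n_iter=200, seed=12)
        K = wm.eigvecs / np.sqrt(wm.eigvals)
        assert amari_index(model.W @ K.T @ A) < 0.1

    def test_plateau_after_long_training(self):
        # convergence claim: the objective trace flattens by 2000 iterations
        X, _ = gen_ica_patches(16, 4000, seed=21)
        Z, _ = whiten(PatchDataset(X, 4, 1.0), 16)
        model = fit_tica(Z, build_topology(4, 4, 3), n_iter=2000, seed=22)
        tr = model.objective_trace
        i0 = int(0.9 * model.n_iter)
        assert abs(tr[-1] - tr[i0]) / abs(tr[i0]) < 1e-4

    def test_unwhitened_input_warns(self):
        rng = np.random.default_rng(5)
        Z = 3.0 * rng.standard_normal((500, 4))
        with pytest.warns(UserWarning, match="whitened"):
            fit_tica(Z, build_topology(2, 2, 1), n_iter=2, seed=0)

    def test_torus_translation_is_topology_symmetry(self):
        # relabeling units by a torus translation permutes H onto itself
        topo = build_topology(6, 6, 3)
        idx = np.arange(36)
        r, c = idx // 6, idx % 6
        perm = ((r + 2) % 6) * 6 + (c + 3) % 6
        np.testing.assert_array_equal(topo.H[np.ix_(perm, perm)], topo.H)

    def test_estimator_protocol(self, whitened_patches):
        from sklearn.base import clone
        _, Z, _ = whitened_patches
        est = TopographicICA(pool_size=3, n_iter=5, random_state=0)
        assert clone(est).get_params() == est.get_params()
        est.fit(Z)
        S = est.transform(Z)
        assert S.shape == Z.shape
        np.testing.assert_allclose(S, Z @ est.components_.T)


class TestReceptiveFields:
    def test_shape_and_whitened_identity(self, whitened_patches):
        _, Z, wm = whitened_patches
        model = fit_tica(Z, build_topology(6, 6, 3), n_iter=10, seed=3)
        A = receptive_fields(model, wm)
        assert A.shape == (256, 36)
        # analyzing the basis in whitened coordinates returns the identity
        back = model.W @ (wm.eigvecs / np.sqrt(wm.eigvals)).T @ A
        np.testing.assert_allclose(back, np.eye(36), atol=1e-8)

    def test_dimension_mismatch_rejected(self, whitened_patches, ica_problem):
        _, Z, wm16 = whitened_patches
        model = fit_tica(Z, build_topology(6, 6, 3), n_iter=5, seed=3)
        _, _, _, wm_other = ica_problem
        with pytest.raises(ValueError):
            receptive_fields(model, wm_other)
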