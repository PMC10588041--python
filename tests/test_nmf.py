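"""The constrained factorization core: scaling, objective, updates, fit,
projection, affectation and their contracts."""

import warnings

import numpy as np
import pytest

from fibrenmf import nmf
from fibrenmf.network import ConstraintMatrix, check_feasibility
from fibrenmf.synthetic import make_profiles

from conftest import h_update_oracle, nnls_ridge_oracle, scaled_objective


def _sv(d):
    d = np.asarray(d, dtype=float)
    return nmf.ScalingVector(d=d, retained=np.arange(d.size), n_features=d.size)


class TestScaling:
    def test_column_l2_norm(self):
        sv = nmf.compute_scaling(np.array([[3.0], [4.0]]))
        assert sv.d[0] == pytest.approx(5.0)

    def test_unit_column(self):
        sv = nmf.compute_scaling(np.array([[1.0], [0.0]]))
        assert sv.d[0] == pytest.approx(1.0)

    def test_zero_column_dropped_and_reported(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="zero-norm"):
            sv = nmf.compute_scaling(X)
        assert list(sv.retained) == [0]
        assert list(sv.dropped) == [1]

    def test_all_zero_errors(self):
        with pytest.raises(nmf.FitError):
            nmf.compute_scaling(np.zeros((2, 2)))


class TestObjective:
    def test_exact_factorization_is_zero(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(size=(4, 2))
        H = rng.uniform(size=(2, 3))
        X = W @ H
        assert nmf.objective(X, W, H, 0.0, nmf.compute_scaling(X)) == pytest.approx(0.0, abs=1e-20)

    def test_scalar_case_hand_value(self):
        # X=2, W=1, H=1, D=2, alpha=1: 0.25 + 1*(1 + 0.25) = 1.5
        X = np.array([[2.0]])
        W = np.array([[1.0]])
        H = np.array([[1.0]])
        D = _sv([2.0])
        val = nmf.objective(X, W, H, 1.0, D)
        assert val == pytest.approx(1.5)
        # cross-check against the independent scripted evaluation
        assert val == pytest.approx(scaled_objective(X / 2.0, W, H / 2.0, 1.0))

    def test_zero_factors_give_scaled_data_norm(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0.1, 1.0, size=(3, 4))
        D = nmf.compute_scaling(X)
        val = nmf.objective(X, np.zeros((3, 2)), np.zeros((2, 4)), 7.0, D)
        assert val == pytest.approx(np.sum((X / D.d) ** 2))

    def test_shape_mismatch_errors(self):
        with pytest.raises(nmf.FitError, match="shape"):
            nmf.objective(np.ones((2, 2)), np.ones((3, 1)), np.ones((1, 2)), 0.0, _sv([1, 1]))


class TestUpdateW:
    def test_identity_profiles_reproduce_data(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(4, 3))
        W = nmf.update_W(X, np.eye(3), 0.0, _sv(np.ones(3)))
        np.testing.assert_allclose(W, X, atol=1e-9)

    def test_scalar_ridge_closed_form(self):
        # w = h*x / (h^2 + alpha) = 0.5 for x=h=d=alpha=1; verify by fine grid
        W = nmf.update_W(np.array([[1.0]]), np.array([[1.0]]), 1.0, _sv([1.0]))
        assert W[0, 0] == pytest.approx(0.5, abs=1e-9)
        grid = np.linspace(0, 1, 100_001)
        vals = (1 - grid) ** 2 + grid**2
        assert abs(grid[np.argmin(vals)] - W[0, 0]) < 1e-4

    def test_active_nonnegativity_matches_qp_oracle(self):
        # two collinear-ish profiles pulling one weight negative
        G = np.array([[1.0, 0.9, 0.8], [1.0, 1.1, 1.2]])
        x = np.array([[1.0, 1.15, 1.3]])
        W = nmf.update_W(x, G, 0.0, _sv(np.ones(3)))
        xo = nnls_ridge_oracle(G.T, x[0], 0.0)
        assert np.all(W >= 0)
        r_ours = np.sum((x[0] - W[0] @ G) ** 2)
        r_oracle = np.sum((x[0] - xo @ G) ** 2)
        assert r_ours <= r_oracle + 1e-8

    def test_all_zero_H_errors(self):
        with pytest.raises(nmf.FitError, match="all zero"):
            nmf.update_W(np.ones((2, 2)), np.zeros((1, 2)), 0.0, _sv(np.ones(2)))


class TestUpdateH:
    def test_identity_weights_reproduce_data(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(3, 4))
        H = nmf.update_H(X, np.eye(3), 0.0, nmf.compute_scaling(X))
        np.testing.assert_allclose(H, X, atol=1e-8)

    def test_constraint_boundary_solution(self):
        # data pull h2 > h1 but F enforces h2 <= h1: optimum on the boundary
        rng = np.random.default_rng(4)
        W = rng.uniform(0.5, 1.0, size=(6, 1))
        X = np.column_stack([0.5 * W[:, 0], 2.0 * W[:, 0]])
        D = _sv(np.ones(2))
        F = ConstraintMatrix(np.array([[-1.0, 1.0]]), ["f0", "f1"])
        H = nmf.update_H(X, W, 0.0, D, F=F)
        assert H[0, 1] <= H[0, 0] + 1e-8
        assert H[0, 1] == pytest.approx(H[0, 0], abs=1e-6)  # active boundary
        Ho = h_update_oracle(X, W, 0.0, A=F.values)
        assert _sse(X, W, H) <= _sse(X, W, Ho) + 1e-6
        # dense 2-D grid search on (h1, h2 = t*h1) region
        best = np.inf
        for h1 in np.linspace(0, 3, 301):
            for h2 in np.linspace(0, 3, 301):
                if h2 <= h1:
                    v = np.sum((X - W @ np.array([[h1, h2]])) ** 2)
                    best = min(best, v)
        assert np.sum((X - W @ H) ** 2) <= best + 1e-6

    def test_huge_alpha_drives_H_to_zero(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(size=(4, 3))
        H = nmf.update_H(X, rng.uniform(size=(4, 2)), 1e6, nmf.compute_scaling(X))
        assert np.all(np.abs(H) < 1e-4)

    def test_all_zero_W_errors(self):
        with pytest.raises(nmf.FitError, match="all zero"):
            nmf.update_H(np.ones((2, 2)), np.zeros((2, 1)), 0.0, _sv(np.ones(2)))


def _sse(X, W, H):
    return float(np.sum((X - W @ H) ** 2))


class TestOracleEquivalence:
    """Both half-updates against the generic QP oracle on random instances."""

    @pytest.mark.parametrize("seed", range(12))
    def test_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        p = int(rng.integers(2, 9))
        k = int(rng.integers(1, 4))
        X = rng.gamma(1.0, size=(n, p)) + 0.01
        D = nmf.compute_scaling(X)
        Y = X / D.d
        alpha = float(rng.uniform(0, 0.5))
        H = rng.uniform(size=(k, p))
        W = nmf.update_W(X, H, alpha, D)
        G = H / D.d
        for s in range(n):
            wo = nnls_ridge_oracle(G.T, Y[s], alpha)
            ours = np.sum((Y[s] - W[s] @ G) ** 2) + alpha * np.sum(W[s] ** 2)
            orac = np.sum((Y[s] - wo @ G) ** 2) + alpha * np.sum(wo**2)
            assert ours <= orac + 1e-6
        # H update with a random valid constraint row set
        W2 = rng.uniform(size=(n, k)) + 0.05
        c = int(rng.integers(1, 4))
        rows = np.zeros((c, p))
        for i in range(c):
            pos, neg = rng.choice(p, size=2, replace=False)
            rows[i, pos], rows[i, neg] = 1.0, -1.0
        F = ConstraintMatrix(rows, [f"f{j}" for j in range(p)])
        Hh = nmf.update_H(X, W2, alpha, D, F=F)
        Gh = Hh / D.d
        Go = h_update_oracle(Y, W2, alpha, A=rows * D.d[None, :])
        ours = np.sum((Y - W2 @ Gh) ** 2) + alpha * np.sum(np.abs(Gh).sum(axis=0) ** 2)
        orac = np.sum((Y - W2 @ Go) ** 2) + alpha * np.sum(np.abs(Go).sum(axis=0) ** 2)
        assert ours <= orac + 1e-6
        assert check_feasibility(Hh, F, tol=1e-6).all_feasible


class TestFit:
    def test_noiseless_recovery(self, toy_network, toy_F):
        H0 = make_profiles(toy_network, toy_F, k=2, seed=0)
        rng = np.random.default_rng(0)
        W0 = rng.gamma(2.0, size=(30, 2))
        X = W0 @ H0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = nmf.fit(X, nmf.Hyperparams(k=2, alpha=1e-3, seed=0, n_restarts=3), toy_F)
        err = np.linalg.norm((X - dec.W @ dec.H) / dec.D.d) / np.linalg.norm(X / dec.D.d)
        assert err < 0.01

    def test_rank_one_monotone_and_converged(self):
        rng = np.random.default_rng(7)
        X = np.outer(rng.uniform(1, 2, 20), rng.uniform(0.1, 1, 6))
        dec = nmf.fit(X, nmf.Hyperparams(k=1, alpha=1e-3, seed=1))
        tr = np.array(dec.objective_trace)
        assert dec.converged
        assert np.all(np.diff(tr) <= 1e-8 * np.abs(tr[:-1]) + 1e-12)

    def test_same_seed_bitwise_identical(self, toy_network, toy_F):
        rng = np.random.default_rng(8)
        X = rng.gamma(1.0, size=(15, toy_network.n_features)) + 0.01
        hp = nmf.Hyperparams(k=2, alpha=1e-2, seed=42, n_restarts=2, max_iter=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = nmf.fit(X, hp, toy_F)
            d2 = nmf.fit(X, hp, toy_F)
        assert np.array_equal(d1.W, d2.W) and np.array_equal(d1.H, d2.H)

    def test_fitted_H_is_feasible(self, toy_network, toy_F):
        rng = np.random.default_rng(9)
        X = rng.gamma(1.0, size=(20, toy_network.n_features)) + 0.01
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = nmf.fit(X, nmf.Hyperparams(k=3, alpha=1e-2, seed=0, n_restarts=2,
                                             max_iter=60), toy_F)
        assert check_feasibility(dec.H, toy_F, tol=1e-6).all_feasible

    def test_scale_equivariance_without_constraints(self):
        # multiplying a feature column by c rescales the H column by c and
        # leaves H D^-1 bitwise invariant (init is drawn in scaled space)
        rng = np.random.default_rng(10)
        X = rng.gamma(1.0, size=(12, 5)) + 0.01
        X2 = X.copy()
        X2[:, 3] *= 7.5
        hp = nmf.Hyperparams(k=2, alpha=0.0, seed=3, n_restarts=1, max_iter=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d1 = nmf.fit(X, hp)
            d2 = nmf.fit(X2, hp)
        G1 = d1.H / d1.D.d
        G2 = d2.H / d2.D.d
        np.testing.assert_allclose(G2, G1, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(d2.H[:, 3], 7.5 * d1.H[:, 3], rtol=1e-9)


class TestProjectAndAffect:
    def test_exact_weight_recovery(self):
        rng = np.random.default_rng(11)
        H = rng.uniform(size=(2, 6))
        w = rng.uniform(0.2, 2.0, size=(5, 2))
        X = w @ H
        D = nmf.compute_scaling(X)
        W = nmf.project(X, H, 0.0, D)
        np.testing.assert_allclose(W, w, atol=1e-8)

    def test_orthogonal_sample_projects_to_zero(self):
        H = np.array([[1.0, 0.0, 0.0]])
        X_new = np.array([[0.0, 1.0, 1.0]])
        D = _sv(np.ones(3))
        W = nmf.project(X_new, H, 0.0, D)
        np.testing.assert_allclose(W, 0.0, atol=1e-9)

    def test_training_projection_is_a_fixed_point(self, toy_network, toy_F):
        rng = np.random.default_rng(12)
        X = rng.gamma(1.0, size=(18, toy_network.n_features)) + 0.01
        hp = nmf.Hyperparams(k=2, alpha=1e-2, seed=5, n_restarts=2, max_iter=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dec = nmf.fit(X, hp, toy_F)
        W = nmf.project(X, dec.H, dec.alpha, dec.D)
        np.testing.assert_allclose(W, dec.W, atol=1e-8)

    def test_feature_mismatch_errors(self):
        with pytest.raises(nmf.FitError, match="feature mismatch"):
            nmf.project(np.ones((2, 3)), np.ones((1, 2)), 0.0, _sv(np.ones(2)))

    def test_noiseless_affectation_recovers_incidence(self):
        rng = np.random.default_rng(13)
        W = rng.gamma(2.0, size=(40, 3))
        B = rng.uniform(size=(3, 8)) * (rng.uniform(size=(3, 8)) < 0.6)
        X = W @ B
        H = nmf.affect_features(X, W, 1e-10)
        np.testing.assert_allclose(H, B, atol=1e-6)

    def test_zero_target_gives_zero_profiles(self):
        H = nmf.affect_features(np.zeros((4, 5)), np.ones((4, 2)), 0.1)
        assert np.all(H == 0)

    def test_transcript_affectation_respects_constraints(self, toy_network, toy_F):
        rng = np.random.default_rng(14)
        W = rng.gamma(2.0, size=(25, 2))
        X = rng.gamma(1.0, size=(25, toy_network.n_features)) + 0.01
        H = nmf.affect_features(X, W, 1e-2, F=toy_F)
        assert check_feasibility(H, toy_F, tol=1e-6).all_feasible

    def test_sample_mismatch_errors(self):
        with pytest.raises(nmf.FitError, match="sample mismatch"):
            nmf.affect_features(np.ones((3, 2)), np.ones((4, 1)), 0.0)


class TestRelativeError:
    def test_exact_reconstruction_zero(self):
        X = np.ones((2, 3))
        err = nmf.relative_error(X, np.ones((2, 1)), np.ones((1, 3)))
        np.testing.assert_allclose(err, 0.0, atol=1e-15)

    def test_zero_model_gives_one(self):
        X = np.ones((2, 3))
        err = nmf.relative_error(X, np.zeros((2, 1)), np.ones((1, 3)))
        np.testing.assert_allclose(err, 1.0)

    def test_hand_value(self):
        X = np.array([[3.0, 4.0]])
        err = nmf.relative_error(X, np.array([[1.0]]), np.array([[3.0, 0.0]]))
        assert err[0] == pytest.approx(0.8)

    def test_zero_sample_is_nan_with_warning(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero-norm"):
            err = nmf.relative_error(X, np.zeros((2, 1)), np.ones((1, 2)))
        assert np.isnan(err[0]) and np.isfinite(err[1])
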