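import dataclasses

import numpy as np
import pytest
import scipy.linalg

from dlnlrr.clustering import assign_labels
from dlnlrr.evaluation import ari
from dlnlrr.graph import gaussian_affinity
from dlnlrr.solver import (
    SolverConfig,
    SolverState,
    fit,
    initialize,
    svt,
    update_H,
    update_J,
    update_W,
    update_Z,
    update_multipliers,
)
from dlnlrr.synthetic import SubspaceSpec, make_subspace_data


def random_state(rng, n=8, r=3, mu=0.7):
    """A structurally valid random solver state."""
    W, _ = np.linalg.qr(rng.standard_normal((n, r)))
    return SolverState(
        J=rng.standard_normal((r, n)),
        Z=rng.standard_normal((n, n)),
        W=W,
        H=np.abs(rng.standard_normal((r, n))),
        Y1=rng.standard_normal((n, n)),
        Y2=rng.standard_normal((r, n)),
        mu=mu,
    )


class TestSvt:
    def test_diagonal_matrix(self):
        out = svt(np.diag([3.0, 1.0, 0.2]), 0.5)
        np.testing.assert_allclose(out, np.diag([2.5, 0.5, 0.0]), atol=1e-12)

    def test_zero_threshold_is_identity(self, rng):
        M = rng.standard_normal((4, 6))
        np.testing.assert_array_equal(svt(M, 0.0), M)

    def test_prox_optimality(self, rng):
        """svt output minimises tau*||J||_* + 1/2 ||J - M||_F^2: the
        subgradient condition holds and no random perturbation does better."""
        for _ in range(10):
            M = rng.standard_normal((5, 4))
            tau = 0.3
            J = svt(M, tau)

            def obj(A):
                return tau * np.linalg.norm(A, ord="nuc") + 0.5 * np.linalg.norm(A - M) ** 2

            # (M - J)/tau must be a nuclear-norm subgradient at J
            D = (M - J) / tau
            U, s, Vt = np.linalg.svd(J, full_matrices=True)
            k = int(np.sum(s > 1e-10))
            Uk, Vk = U[:, :k], Vt[:k].T
            np.testing.assert_allclose(Uk.T @ D @ Vk, np.eye(k), atol=1e-8)
            P_u = np.eye(5) - Uk @ Uk.T
            P_v = np.eye(4) - Vk @ Vk.T
            W = P_u @ D @ P_v
            assert np.linalg.norm(W, 2) <= 1 + 1e-8
            # and beats random perturbations
            base = obj(J)
            for _ in range(200):
                assert base <= obj(J + 0.1 * rng.standard_normal(J.shape)) + 1e-12

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            svt(np.array([[np.nan, 1.0]]), 0.1)


class TestUpdateJ:
    def test_zero_state(self, rng):
        st = random_state(rng)
        st.H = np.zeros_like(st.H)
        st.Y2 = np.zeros_like(st.Y2)
        np.testing.assert_array_equal(update_J(st, SolverConfig(r=3)), 0.0)

    def test_lambda_zero_passthrough(self, rng):
        st = random_state(rng)
        cfg = SolverConfig(r=3, lam=0.0)
        np.testing.assert_allclose(update_J(st, cfg), st.H - st.Y2 / st.mu)

    def test_decreases_subobjective(self, rng):
        st = random_state(rng)
        cfg = SolverConfig(r=3, lam=0.8)

        def sub(J):
            return (
                cfg.lam * np.linalg.norm(J, ord="nuc")
                + np.sum(st.Y2 * (J - st.H))
                + st.mu / 2 * np.linalg.norm(J - st.H) ** 2
            )

        assert sub(update_J(st, cfg)) <= sub(st.J) + 1e-10


class TestUpdateZ:
    def test_data_term_vanishes(self, rng):
        st = random_state(rng)
        X = np.zeros((6, 8))
        np.testing.assert_allclose(update_Z(st, X), st.W @ st.H - st.Y1 / st.mu)

    def test_large_mu_limit(self, rng):
        st = random_state(rng)
        st.mu = 1e12
        X = rng.standard_normal((6, 8))
        np.testing.assert_allclose(update_Z(st, X), st.W @ st.H, atol=1e-6)

    def test_zeroes_subproblem_gradient(self, rng):
        st = random_state(rng)
        X = rng.standard_normal((6, 8))
        Z = update_Z(st, X)
        grad = X.T @ X @ Z - X.T @ X + st.Y1 + st.mu * (Z - st.W @ st.H)
        assert np.linalg.norm(grad) <= 1e-8 * (1 + np.linalg.norm(Z))
        # finite-difference check of the scalar subobjective along random dirs
        def f(A):
            return (
                0.5 * np.linalg.norm(X - X @ A) ** 2
                + np.sum(st.Y1 * (A - st.W @ st.H))
                + st.mu / 2 * np.linalg.norm(A - st.W @ st.H) ** 2
            )

        eps = 1e-6
        for _ in range(5):
            D = rng.standard_normal(Z.shape)
            deriv = (f(Z + eps * D) - f(Z - eps * D)) / (2 * eps)
            assert abs(deriv) <= 1e-4 * (1 + abs(f(Z)))

    def test_printed_factor_two_variant(self, rng):
        st = random_state(rng)
        X = rng.standard_normal((6, 8))
        cfg = SolverConfig(r=3, data_grad_factor=2.0)
        Z = update_Z(st, X, cfg)
        G = X.T @ X
        lhs = (2 * G + st.mu * np.eye(8)) @ Z
        rhs = 2 * G + st.mu * st.W @ st.H - st.Y1
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestUpdateW:
    def test_identity_fixed_point(self, rng):
        st = random_state(rng, n=5, r=3)
        Q, _ = np.linalg.qr(rng.standard_normal((5, 3)))
        st.H = np.eye(3, 8)[:, :8]
        # H = I_r (padded): W should reproduce the orthonormal Q
        st.H = np.hstack([np.eye(3), np.zeros((3, 2))])
        st.Z = Q @ st.H
        st.Y1 = np.zeros_like(st.Z)
        W = update_W(st)
        np.testing.assert_allclose(W @ st.H, st.Z, atol=1e-10)

    def test_orthonormal_columns(self, rng):
        st = random_state(rng)
        W = update_W(st)
        np.testing.assert_allclose(W.T @ W, np.eye(3), atol=1e-10)

    def test_beats_random_orthonormal_candidates(self, rng):
        for _ in range(20):
            st = random_state(rng, n=8, r=3)
            W = update_W(st)
            Q = st.Z + st.Y1 / st.mu
            best = np.linalg.norm(W @ st.H - Q)
            for _ in range(500):
                C, _ = np.linalg.qr(rng.standard_normal((8, 3)))
                assert best <= np.linalg.norm(C @ st.H - Q) + 1e-10


class TestUpdateH:
    def test_scalar_sylvester(self):
        # 1x1 problem: a h + h b + q = 0  ->  h = -q/(a+b), before projection
        st = SolverState(
            J=np.array([[2.0]]),
            Z=np.array([[1.5]]),
            W=np.array([[1.0]]),
            H=np.array([[0.0]]),
            Y1=np.array([[0.3]]),
            Y2=np.array([[0.2]]),
            mu=0.9,
        )
        L = np.array([[0.5]])
        cfg = SolverConfig(r=1, beta=0.7)
        a = st.mu * 2.0
        b = 2 * cfg.beta * 0.5
        q = st.Y2[0, 0] - st.mu * st.Z[0, 0] - st.Y1[0, 0] - st.mu * st.J[0, 0]
        H = update_H(st, L, cfg, project=False)
        assert H[0, 0] == pytest.approx(-q / (a + b), rel=1e-12)

    def test_beta_zero_direct_solve(self, rng):
        st = random_state(rng)
        cfg = SolverConfig(r=3, beta=0.0)
        L = np.zeros((8, 8))
        H = update_H(st, L, cfg, project=False)
        A = st.mu * (st.W.T @ st.W + np.eye(3))
        rhs = st.mu * st.W.T @ st.Z + st.W.T @ st.Y1 + st.mu * st.J - st.Y2
        np.testing.assert_allclose(H, np.linalg.solve(A, rhs), atol=1e-10)

    def test_matches_scipy_sylvester_oracle(self, rng):
        """Closed-form eigenbasis solve == scipy.linalg.solve_sylvester."""
        for _ in range(5):
            st = random_state(rng, n=6, r=3)
            S = np.abs(rng.standard_normal((6, 6)))
            S = 0.5 * (S + S.T)
            np.fill_diagonal(S, 0)
            L = np.diag(S.sum(1)) - S
            cfg = SolverConfig(r=3, beta=1.3)
            H = update_H(st, L, cfg, project=False)
            A = st.mu * (st.W.T @ st.W + np.eye(3))
            B = 2 * cfg.beta * L
            Q = st.Y2 - st.mu * st.W.T @ st.Z - st.W.T @ st.Y1 - st.mu * st.J
            H_ref = scipy.linalg.solve_sylvester(A, B, -Q)
            np.testing.assert_allclose(H, H_ref, atol=1e-8)
            resid = np.linalg.norm(A @ H + H @ B + Q)
            assert resid <= 1e-8 * (1 + np.linalg.norm(Q))

    def test_projection_nonnegative(self, rng):
        st = random_state(rng)
        H = update_H(st, np.zeros((8, 8)), SolverConfig(r=3))
        assert H.min() >= 0


class TestMultipliers:
    def test_zero_residual_leaves_multipliers(self, rng):
        st = random_state(rng)
        st.Z = st.W @ st.H
        st.J = st.H.copy()
        Y1, Y2, _ = update_multipliers(st, SolverConfig(r=3))
        np.testing.assert_array_equal(Y1, st.Y1)
        np.testing.assert_array_equal(Y2, st.Y2)

    def test_rho_one_keeps_mu(self, rng):
        st = random_state(rng, mu=0.5)
        *_, mu = update_multipliers(st, SolverConfig(r=3, rho=1.0))
        assert mu == 0.5

    def test_mu_ceiling(self, rng):
        st = random_state(rng, mu=1e6)
        *_, mu = update_multipliers(st, SolverConfig(r=3, rho=2.0, mu_max=1e6))
        assert mu == 1e6


class TestFit:
    def test_constraints_and_convergence(self, subspace_instance):
        X, labels, g, cfg = subspace_instance
        st = fit(X, g.L, cfg)
        assert st.converged and st.iter <= 500
        np.testing.assert_allclose(st.W.T @ st.W, np.eye(3), atol=1e-8)
        assert st.H.min() >= 0
        r1, r2, _ = st.residuals[-1]
        assert r1 / max(1, np.linalg.norm(st.Z)) <= 1e-4
        assert r2 / max(1, np.linalg.norm(st.J)) <= 1e-4

    def test_same_seed_bitwise_identical(self, subspace_instance):
        X, _, g, cfg = subspace_instance
        a = fit(X, g.L, cfg)
        b = fit(X, g.L, cfg)
        assert a.residuals == b.residuals
        np.testing.assert_array_equal(a.H, b.H)

    def test_monotone_residual_tail(self, subspace_instance):
        X, _, g, cfg = subspace_instance
        st = fit(X, g.L, cfg)
        r1 = [r[0] for r in st.residuals]
        tail = r1[len(r1) // 2 :]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(tail, tail[1:]))

    def test_single_cluster_r1(self):
        rng = np.random.default_rng(3)
        base = np.abs(rng.standard_normal(10))
        X = np.outer(base, np.abs(rng.standard_normal(15)))
        st = fit(X, np.zeros((15, 15)), SolverConfig(r=1, beta=0.0, seed=0))
        assert st.H.shape == (1, 15)
        assert np.all(assign_labels(st.H) == 1)

    def test_nan_input_rejected(self):
        X = np.ones((4, 6))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit(X, np.zeros((6, 6)), SolverConfig(r=2))

    def test_divergent_iterate_names_variable_and_iteration(self):
        from dlnlrr.solver import _check_finite

        with pytest.raises(FloatingPointError, match=r"Z at iteration 7"):
            _check_finite("Z", np.array([np.inf]), 7)

    def test_r_too_large(self):
        with pytest.raises(ValueError):
            fit(np.ones((3, 5)), np.zeros((5, 5)), SolverConfig(r=4))

    def test_scaling_equivariance(self):
        """Scaling X by c>0 with (lambda, beta, mu0, mu_max) scaled by c^2
        and kernel width by c reproduces the same labels."""
        X, labels = make_subspace_data(SubspaceSpec(r=3, d=2, m=30, n_per=30, noise_sd=0.01, seed=4))
        c = 2.0
        g1 = gaussian_affinity(X, t=1.0)
        g2 = gaussian_affinity(c * X, t=c * 1.0)
        cfg1 = SolverConfig(r=3, lam=1.0, beta=7.0, seed=4)
        cfg2 = dataclasses.replace(
            cfg1, lam=c**2, beta=7.0 * c**2, mu0=cfg1.mu0 * c**2, mu_max=cfg1.mu_max * c**2
        )
        lab1 = assign_labels(fit(X, g1.L, cfg1).H)
        lab2 = assign_labels(fit(c * X, g2.L, cfg2).H)
        assert ari(lab1, lab2) == pytest.approx(1.0)


class TestAblation:
    def test_frozen_dictionary_keeps_initial_W(self, subspace_instance):
        X, _, g, cfg = subspace_instance
        cfg = dataclasses.replace(cfg, learn_dictionary=False, max_iter=30)
        st = fit(X, g.L, cfg)
        W0 = initialize(X.shape[1], cfg).W
        np.testing.assert_array_equal(st.W, W0)
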