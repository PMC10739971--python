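"""Variational updates and the full supervised projection."""

import numpy as np
import pytest

from mda import evaluation as ev
from mda import projection as pr
from mda.projection import CapacityError, Hyperparams, ProjectionError


def small_problem(seed=0, m=6, n=20, K=3, R=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, n))
    c = rng.integers(1, K + 1, size=n)
    for k in range(1, K + 1):  # every class occupied
        c[k - 1] = k
    hyper = Hyperparams(R=R, seed=seed, max_iter=10, mc_samples=100)
    return X, c, hyper


class TestInit:
    def test_same_seed_identical(self):
        X, c, hyper = small_problem()
        a = pr.init_state(X, c, hyper)
        b = pr.init_state(X, c, hyper)
        assert np.array_equal(a.mu_Q, b.mu_Q)
        assert np.array_equal(a.t_mean, b.t_mean)

    def test_different_seeds_differ(self):
        X, c, _ = small_problem()
        a = pr.init_state(X, c, Hyperparams(R=4, seed=1))
        b = pr.init_state(X, c, Hyperparams(R=4, seed=2))
        assert not np.array_equal(a.mu_Q, b.mu_Q)

    def test_initial_scores_respect_margin(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        own = st.t_mean[np.arange(len(c)), c - 1]
        masked = st.t_mean.copy()
        masked[np.arange(len(c)), c - 1] = -np.inf
        assert np.all(own > masked.max(axis=1))

    def test_k_exceeds_n_rejected(self):
        X = np.zeros((3, 2))
        with pytest.raises(ProjectionError):
            pr.init_state(X, np.array([1, 3]), Hyperparams(R=2))

    def test_nonfinite_rejected(self):
        X = np.full((3, 4), np.nan)
        with pytest.raises(ProjectionError):
            pr.init_state(X, np.array([1, 1, 1, 1]), Hyperparams(R=2))


class TestUpdatePhi:
    def test_substitution_zero(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        st.mu_Q[:] = 0.0
        st.cov_Q[:] = 0.0
        pr.update_phi(st, hyper)
        assert np.all(st.phi_shape == 1.5)
        assert np.allclose(st.phi_scale, 1.0)

    def test_substitution_two(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        st.mu_Q[:] = np.sqrt(2.0)
        st.cov_Q[:] = 0.0
        pr.update_phi(st, hyper)
        assert np.allclose(st.phi_scale, 0.5)

    def test_scale_decreasing_in_eq2(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        st.cov_Q[:] = 0.0
        scales = []
        for v in (0.0, 1.0, 3.0):
            st.mu_Q[:] = v
            pr.update_phi(st, hyper)
            scales.append(st.phi_scale[0, 0])
        assert scales[0] > scales[1] > scales[2]


class TestUpdateQ:
    def test_zero_data_prior_only(self):
        X, c, hyper = small_problem()
        st = pr.init_state(np.zeros_like(X), c, hyper)
        pr.update_phi(st, hyper)
        pr.update_Q(st, np.zeros_like(X))
        assert np.allclose(st.mu_Q, 0.0)
        for s in range(hyper.R):
            assert np.allclose(
                st.cov_Q[s], np.diag(1.0 / st.phi_tilde[:, s]), atol=1e-6
            )

    def test_strong_prior_shrinks_mean(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        st.phi_shape[:] = 1e8
        st.phi_scale[:] = 1.0
        pr.update_Q(st, X)
        assert np.abs(st.mu_Q).max() < 1e-4

    def test_matches_explicit_inverse_oracle(self):
        X, c, hyper = small_problem(seed=4)
        st = pr.init_state(X, c, hyper)
        pr.update_phi(st, hyper)
        pr.update_Q(st, X)
        for s in range(hyper.R):
            prec = np.diag(st.phi_tilde[:, s]) + X @ X.T + 1e-8 * np.eye(X.shape[0])
            cov = np.linalg.inv(prec)
            assert np.allclose(st.cov_Q[s], cov, atol=1e-10)
            assert np.allclose(st.mu_Q[:, s], cov @ X @ st.mu_Z[s], atol=1e-10)

    def test_capacity_guard(self):
        hyper = Hyperparams(R=2, m_max=10)
        X = np.zeros((11, 5))
        with pytest.raises(CapacityError):
            pr.init_state(X, np.array([1, 1, 1, 1, 1]), hyper)


class TestUpdateZ:
    def test_no_weights_reduces_to_projection(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        st.mu_bw[:, 1:] = 0.0
        st.cov_bw[:] = 0.0
        st.mu_bw[:, 0] = 0.0
        pr.update_Z(st, X)
        assert np.allclose(st.cov_Z, np.eye(hyper.R), atol=1e-6)
        assert np.allclose(st.mu_Z, st.cov_Z @ (st.mu_Q.T @ X), atol=1e-12)

    def test_matches_inverse_oracle(self):
        X, c, hyper = small_problem(seed=9)
        st = pr.init_state(X, c, hyper)
        pr.update_Z(st, X)
        e_wwt = np.zeros((hyper.R, hyper.R))
        for e in range(st.mu_bw.shape[0]):
            w = st.mu_bw[e, 1:]
            e_wwt += np.outer(w, w) + st.cov_bw[e, 1:, 1:]
        cov = np.linalg.inv(np.eye(hyper.R) + e_wwt + 1e-8 * np.eye(hyper.R))
        assert np.allclose(st.cov_Z, cov, atol=1e-10)


class TestUpdatePriorsAndBW:
    def test_lambda_substitution(self):
        X, c, hyper = small_problem()
        st = pr.init_state(X, c, hyper)
        st.mu_bw[:, 0] = 1.0
        st.cov_bw[:, 0, 0] = 1.0  # E[b^2] = 2
        pr.update_priors_and_bW(st, hyper)
        assert np.all(st.lambda_shape == 1.5)
        # scale recomputed from the pre-update E[b^2]
        assert np.allclose(st.lambda_scale, 0.5)

    def test_psi_scale_shrinks_with_weight_magnitude(self):
        X, c, hyper = small_problem()
        st1 = pr.init_state(X, c, hyper)
        st1.mu_bw[:, 1:] = 0.1
        st1.cov_bw[:] = 0.0
        pr.update_priors_and_bW(st1, hyper)
        st2 = pr.init_state(X, c, hyper)
        st2.mu_bw[:, 1:] = 5.0
        st2.cov_bw[:] = 0.0
        pr.update_priors_and_bW(st2, hyper)
        assert np.all(st2.psi_scale < st1.psi_scale)

    def test_single_class_zero_Z_block_structure(self):
        # K = 1, R = 1, Z mean zero, n = 4: the joint precision decouples into
        # lambda~ + n and diag(psi~) + n cov_Z, checked against hand algebra
        rng = np.random.default_rng(0)
        X = rng.normal(size=(2, 4))
        c = np.ones(4, dtype=int)
        hyper = Hyperparams(R=1, seed=0)
        st = pr.init_state(X, c, hyper)
        st.mu_Z[:] = 0.0
        st.cov_Z = np.array([[0.5]])
        pr.update_priors_and_bW(st, hyper)
        lam = st.lambda_tilde[0]
        psi = st.psi_tilde[0, 0]
        expect_prec = np.array([[lam + 4.0, 0.0], [0.0, psi + 4 * 0.5]])
        assert np.allclose(
            st.cov_bw[0], np.linalg.inv(expect_prec + 1e-8 * np.eye(2)), atol=1e-10
        )


class TestUpdateT:
    def test_single_class_exact_untruncated_mean(self):
        X, c, hyper = small_problem(K=1)
        c = np.ones_like(c)
        st = pr.init_state(X, c, hyper)
        pr.update_T(st, c, hyper)
        expect = st.mu_Z.T @ st.W_tilde + st.b_tilde
        assert np.array_equal(st.t_mean, expect)

    def test_two_class_symmetric_means_split(self):
        rng = np.random.default_rng(1)
        n = 200
        X = rng.normal(size=(3, n))
        c = np.tile([1, 2], n // 2)
        hyper = Hyperparams(R=2, seed=1, mc_samples=500)
        st = pr.init_state(X, c, hyper)
        st.mu_Z[:] = 0.0
        st.mu_bw[:] = 0.0  # untruncated means all zero
        pr.update_T(st, c, hyper)
        own = st.t_mean[np.arange(n), c - 1]
        other = st.t_mean[np.arange(n), 2 - c]
        assert np.all(own > 0) and np.all(other < 0)

    def test_three_class_matches_rejection_oracle(self):
        n, K = 5, 3
        c = np.array([1, 2, 3, 1, 2])
        X = np.zeros((2, n))
        hyper = Hyperparams(R=2, seed=3, mc_samples=300_000)
        st = pr.init_state(X, c, hyper)
        st.mu_Z[:] = 0.0
        st.mu_bw[:] = 0.0
        pr.update_T(st, c, hyper)
        # independent large-sample rejection oracle at mean zero
        rng = np.random.default_rng(99)
        draws = rng.standard_normal((2_000_000, K))
        top = draws.argmax(axis=1)
        for i in range(n):
            sel = draws[top == c[i] - 1]
            assert np.allclose(st.t_mean[i], sel.mean(axis=0), atol=0.01)

    def test_truncation_respected_in_expectation(self):
        X, c, hyper = small_problem(seed=6)
        st = pr.init_state(X, c, hyper)
        pr.update_T(st, c, hyper)
        own = st.t_mean[np.arange(len(c)), c - 1]
        masked = st.t_mean.copy()
        masked[np.arange(len(c)), c - 1] = -np.inf
        assert np.all(own >= masked.max(axis=1))


class TestFit:
    def test_single_class_zero_data_fully_shrunk(self):
        X = np.zeros((4, 8))
        c = np.ones(8, dtype=int)
        _, proj = pr.fit(X, c, Hyperparams(R=3, seed=0, max_iter=5),
                         standardize=False)
        assert np.allclose(proj.mu_Q, 0.0)
        assert np.allclose(proj.U, 0.0)

    def test_deterministic_given_seed(self):
        X, c, hyper = small_problem(seed=2)
        _, p1 = pr.fit(X, c, hyper)
        _, p2 = pr.fit(X, c, hyper)
        assert np.array_equal(p1.U, p2.U)

    def test_gamma_shapes_and_covariances_each_cycle(self):
        X, c, hyper = small_problem(seed=5)
        st = pr.init_state(X, c, hyper)
        for _ in range(4):
            pr.update_phi(st, hyper)
            pr.update_Q(st, X)
            pr.update_Z(st, X)
            pr.update_priors_and_bW(st, hyper)
            pr.update_T(st, c, hyper)
            assert np.all(st.phi_shape == hyper.alpha_phi + 0.5)
            assert np.all(st.lambda_shape == hyper.alpha_lambda + 0.5)
            assert np.all(st.psi_shape == hyper.alpha_psi + 0.5)
            for cov in (st.cov_Z, *st.cov_Q, *st.cov_bw):
                assert np.allclose(cov, cov.T, atol=1e-10)
                assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_shuffled_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(21)
        n, m = 200, 10
        X = rng.normal(size=(m, n))
        c = np.tile([1, 2], n // 2)
        c = rng.permutation(c)
        _, proj = pr.fit(X, c, Hyperparams(R=4, seed=21, max_iter=30))
        acc = ev.knn_accuracy(proj.U, c, seed=0)
        assert abs(acc - 0.5) <= 0.15


class TestTransform:
    def test_identity_features_recover_muQ(self):
        mu_Q = np.random.default_rng(0).normal(size=(5, 3))
        assert np.array_equal(pr.transform(np.eye(5), mu_Q), mu_Q)

    def test_zero_matrix(self):
        mu_Q = np.ones((4, 2))
        assert np.all(pr.transform(np.zeros((4, 7)), mu_Q) == 0)

    def test_matches_hand_product(self, rng):
        X = rng.normal(size=(6, 9))
        mu_Q = rng.normal(size=(6, 2))
        assert np.allclose(pr.transform(X, mu_Q), X.T @ mu_Q)

    def test_dimension_mismatch(self):
        with pytest.raises(ProjectionError):
            pr.transform(np.zeros((3, 2)), np.zeros((4, 2)))
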