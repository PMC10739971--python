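"""Supervised Bayesian dimensionality reduction by variational inference.

A linear projection Q (m features x R components) is inferred jointly with
projected coordinates Z, per-class weights/biases (W, b) that score the
pseudo-label classes, and sparsity-inducing gamma precisions (Phi over Q,
lambda over b, Psi over W).  Class membership enters through truncated-
normal score variables T: each sample's own-class score is constrained to
exceed all others, which pulls samples sharing a pseudo-label together in
the projected space while the X Xᵀ term in the Q update preserves overall
variance, PCA-style.

All posterior factors are updated by coordinate ascent on the variational
objective; truncated-normal expectations are estimated by seeded rejection
sampling.  The projected data is U = Xᵀ E[Q].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "Hyperparams",
    "VariationalState",
    "Projection",
    "init_state",
    "update_phi",
    "update_Q",
    "update_Z",
    "update_priors_and_bW",
    "update_T",
    "fit",
    "transform",
]

_JITTER = 1e-8


class ProjectionError(ValueError):
    """Invalid input to the Bayesian projection."""


class CapacityError(ProjectionError):
    """Feature dimensionality exceeds the dense-covariance guard."""


@dataclass(frozen=True)
class Hyperparams:
    """Gamma hyperparameters and fitting controls.

    Shapes/scales follow the (shape, scale) gamma convention; posterior
    expectations of gamma variables are shape * scale.  Defaults: all six
    gamma parameters 1, projection dimension R = 16, at most 200
    coordinate-ascent cycles.
    """

    alpha_lambda: float = 1.0
    beta_lambda: float = 1.0
    alpha_phi: float = 1.0
    beta_phi: float = 1.0
    alpha_psi: float = 1.0
    beta_psi: float = 1.0
    R: int = 16
    max_iter: int = 200
    tol: float = 1e-4
    mc_samples: int = 200
    seed: int = 0
    m_max: int = 2000

    def __post_init__(self):
        for name in ("alpha_lambda", "beta_lambda", "alpha_phi",
                     "beta_phi", "alpha_psi", "beta_psi"):
            if getattr(self, name) <= 0:
                raise ProjectionError(f"{name} must be > 0")
        if self.R < 1:
            raise ProjectionError("R must be >= 1")


@dataclass
class VariationalState:
    """Sufficient statistics of every factored posterior.

    Gamma factors store (shape, scale) arrays; normal factors store means
    and covariances.  ``t_mean`` holds the Monte-Carlo estimate of the
    truncated-normal score means.
    """

    # q(Phi): m x R gamma
    phi_shape: np.ndarray
    phi_scale: np.ndarray
    # q(Q): per-component mean columns (m x R) and covariances (R x m x m)
    mu_Q: np.ndarray
    cov_Q: np.ndarray
    # q(Z): mean (R x n), shared covariance (R x R)
    mu_Z: np.ndarray
    cov_Z: np.ndarray
    # q(lambda): K gamma
    lambda_shape: np.ndarray
    lambda_scale: np.ndarray
    # q(Psi): R x K gamma
    psi_shape: np.ndarray
    psi_scale: np.ndarray
    # q(b, W): per class joint mean (K x (R+1)) and covariance (K x (R+1) x (R+1))
    mu_bw: np.ndarray
    cov_bw: np.ndarray
    # q(T): n x K posterior score means
    t_mean: np.ndarray
    rng: np.random.Generator = field(repr=False, default=None)

    @property
    def phi_tilde(self) -> np.ndarray:
        return self.phi_shape * self.phi_scale

    @property
    def lambda_tilde(self) -> np.ndarray:
        return self.lambda_shape * self.lambda_scale

    @property
    def psi_tilde(self) -> np.ndarray:
        return self.psi_shape * self.psi_scale

    @property
    def b_tilde(self) -> np.ndarray:
        return self.mu_bw[:, 0]

    @property
    def W_tilde(self) -> np.ndarray:
        """R x K posterior mean of the weight matrix."""
        return self.mu_bw[:, 1:].T


@dataclass(frozen=True)
class Projection:
    """Fitted projection: posterior mean of Q and the projected data U = Xᵀ mu_Q."""

    mu_Q: np.ndarray
    U: np.ndarray
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None


def _validate_inputs(X: np.ndarray, c: np.ndarray, hyper: Hyperparams) -> int:
    if not np.isfinite(X).all():
        raise ProjectionError("non-finite values in feature matrix X")
    m, n = X.shape
    if m > hyper.m_max:
        raise CapacityError(
            f"feature dimension m={m} exceeds m_max={hyper.m_max}; the Q update "
            "forms an m x m covariance — reduce features (e.g. PCA) first"
        )
    c = np.asarray(c)
    K = int(c.max())
    if c.min() < 1 or set(np.unique(c)) != set(range(1, K + 1)):
        raise ProjectionError("labels c must occupy every value of 1..K")
    if K > n:
        raise ProjectionError(f"more classes ({K}) than samples ({n})")
    return K


def init_state(X: np.ndarray, c: np.ndarray, hyper: Hyperparams) -> VariationalState:
    """Seeded random initialization of every posterior factor."""
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=int)
    K = _validate_inputs(X, c, hyper)
    m, n = X.shape
    R = hyper.R
    rng = np.random.default_rng(hyper.seed)

    mu_Q = rng.normal(0.0, 0.1, size=(m, R))
    cov_Q = np.broadcast_to(np.eye(m), (R, m, m)).copy()
    mu_Z = rng.normal(0.0, 1.0, size=(R, n))
    cov_Z = np.eye(R)
    mu_bw = rng.normal(0.0, 0.1, size=(K, R + 1))
    cov_bw = np.broadcast_to(np.eye(R + 1), (K, R + 1, R + 1)).copy()

    # untruncated score guess, then enforce the own-class margin
    t_mean = mu_Z.T @ mu_bw[:, 1:].T + mu_bw[:, 0]
    if K > 1:
        idx = np.arange(n)
        others = t_mean.copy()
        others[idx, c - 1] = -np.inf
        t_mean[idx, c - 1] = others.max(axis=1) + 1.0

    return VariationalState(
        phi_shape=np.full((m, R), hyper.alpha_phi),
        phi_scale=np.full((m, R), hyper.beta_phi),
        mu_Q=mu_Q,
        cov_Q=cov_Q,
        mu_Z=mu_Z,
        cov_Z=cov_Z,
        lambda_shape=np.full(K, hyper.alpha_lambda),
        lambda_scale=np.full(K, hyper.beta_lambda),
        psi_shape=np.full((R, K), hyper.alpha_psi),
        psi_scale=np.full((R, K), hyper.beta_psi),
        mu_bw=mu_bw,
        cov_bw=cov_bw,
        t_mean=t_mean,
        rng=rng,
    )


def update_phi(state: VariationalState, hyper: Hyperparams) -> VariationalState:
    """Gamma update of the precisions over Q entries."""
    e_q2 = state.mu_Q**2 + np.diagonal(state.cov_Q, axis1=1, axis2=2).T  # m x R
    state.phi_shape = np.full_like(e_q2, hyper.alpha_phi + 0.5)
    state.phi_scale = 1.0 / (1.0 / hyper.beta_phi + e_q2 / 2.0)
    return state


def _spd_solve(prec: np.ndarray, rhs: np.ndarray, what: str) -> np.ndarray:
    prec = prec + _JITTER * np.eye(prec.shape[0])
    try:
        cf = cho_factor(prec, lower=True)
    except np.linalg.LinAlgError as err:
        raise ProjectionError(f"non-positive-definite precision in {what}") from err
    return cho_solve(cf, rhs)


def update_Q(state: VariationalState, X: np.ndarray) -> VariationalState:
    """Normal update of each projection column q_s."""
    m, _ = X.shape
    xxt = X @ X.T
    phi_t = state.phi_tilde
    eye = np.eye(m)
    for s in range(state.mu_Q.shape[1]):
        prec = np.diag(phi_t[:, s]) + xxt
        cov = _spd_solve(prec, eye, "q(Q)")
        cov = (cov + cov.T) / 2.0
        state.cov_Q[s] = cov
        state.mu_Q[:, s] = cov @ (X @ state.mu_Z[s])
    return state


def update_Z(state: VariationalState, X: np.ndarray) -> VariationalState:
    """Normal update of the projected coordinates; covariance shared over samples."""
    R = state.mu_Z.shape[0]
    W = state.W_tilde  # R x K
    e_wwt = np.zeros((R, R))
    for e in range(state.mu_bw.shape[0]):
        w_e = state.mu_bw[e, 1:]
        e_wwt += np.outer(w_e, w_e) + state.cov_bw[e, 1:, 1:]
    prec = np.eye(R) + e_wwt
    cov = _spd_solve(prec, np.eye(R), "q(Z)")
    cov = (cov + cov.T) / 2.0
    state.cov_Z = cov
    rhs = state.mu_Q.T @ X + W @ (state.t_mean.T - state.b_tilde[:, None])
    state.mu_Z = cov @ rhs
    return state


def update_priors_and_bW(state: VariationalState, hyper: Hyperparams) -> VariationalState:
    """Gamma updates of lambda and Psi, then the joint normal update of (b_e, w_e)."""
    K = state.mu_bw.shape[0]
    R = state.mu_Z.shape[0]
    n = state.mu_Z.shape[1]

    e_b2 = state.mu_bw[:, 0] ** 2 + state.cov_bw[:, 0, 0]
    state.lambda_shape = np.full(K, hyper.alpha_lambda + 0.5)
    state.lambda_scale = 1.0 / (1.0 / hyper.beta_lambda + e_b2 / 2.0)

    e_w2 = state.mu_bw[:, 1:] ** 2 + np.diagonal(
        state.cov_bw[:, 1:, 1:], axis1=1, axis2=2
    )  # K x R
    state.psi_shape = np.full((R, K), hyper.alpha_psi + 0.5)
    state.psi_scale = 1.0 / (1.0 / hyper.beta_psi + e_w2.T / 2.0)

    e_zzt = state.mu_Z @ state.mu_Z.T + n * state.cov_Z
    z_sum = state.mu_Z.sum(axis=1)
    lam_t = state.lambda_tilde
    psi_t = state.psi_tilde
    for e in range(K):
        prec = np.empty((R + 1, R + 1))
        prec[0, 0] = lam_t[e] + n
        prec[0, 1:] = z_sum
        prec[1:, 0] = z_sum
        prec[1:, 1:] = np.diag(psi_t[:, e]) + e_zzt
        cov = _spd_solve(prec, np.eye(R + 1), "q(b,W)")
        cov = (cov + cov.T) / 2.0
        t_e = state.t_mean[:, e]
        rhs = np.concatenate(([t_e.sum()], state.mu_Z @ t_e))
        state.cov_bw[e] = cov
        state.mu_bw[e] = cov @ rhs
    return state


def update_T(
    state: VariationalState,
    c: np.ndarray,
    hyper: Hyperparams,
    max_rounds: int = 20,
) -> VariationalState:
    """Monte-Carlo update of the truncated-normal score means.

    Draws from N(untruncated mean, I) and keeps draws whose own-class
    coordinate is strictly maximal.  Samples with no accepted draw after
    ``max_rounds`` rounds fall back to their single best-margin draw.
    K = 1 has a vacuous truncation and is handled exactly.
    """
    c = np.asarray(c, dtype=int)
    n, K = state.t_mean.shape[0], state.mu_bw.shape[0]
    mean = state.mu_Z.T @ state.W_tilde + state.b_tilde  # n x K
    if K == 1:
        state.t_mean = mean.copy()
        return state

    rng = state.rng if state.rng is not None else np.random.default_rng(hyper.seed)
    own = c - 1
    pending = np.arange(n)
    t_new = np.empty_like(mean)
    best_margin = np.full(n, -np.inf)
    best_draw = mean.copy()

    for _ in range(max_rounds):
        if pending.size == 0:
            break
        mu_p = mean[pending]  # p x K
        draws = rng.standard_normal((pending.size, hyper.mc_samples, K)) + mu_p[:, None, :]
        own_p = own[pending]
        own_scores = draws[np.arange(pending.size), :, own_p]  # p x mc
        masked = draws.copy()
        masked[np.arange(pending.size), :, own_p] = -np.inf
        rival = masked.max(axis=2)  # p x mc
        accept = own_scores > rival
        margins = own_scores - rival
        # remember the best-margin draw in case acceptance never happens
        arg = margins.argmax(axis=1)
        better = margins[np.arange(pending.size), arg] > best_margin[pending]
        upd = pending[better]
        best_margin[upd] = margins[np.arange(pending.size), arg][better]
        best_draw[upd] = draws[np.arange(pending.size), arg][better]

        n_acc = accept.sum(axis=1)
        done = n_acc > 0
        if done.any():
            acc = accept[done][:, :, None]
            sums = (draws[done] * acc).sum(axis=1)
            t_new[pending[done]] = sums / n_acc[done][:, None]
        pending = pending[~done]

    if pending.size:
        t_new[pending] = best_draw[pending]
    state.t_mean = t_new
    return state


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=1, keepdims=True)
    std = X.std(axis=1, keepdims=True)
    std = np.where(std < 1e-12, 1.0, std)
    return (X - mean) / std, mean.ravel(), std.ravel()


def fit(
    X: np.ndarray,
    c: np.ndarray,
    hyper: Hyperparams | None = None,
    standardize: bool = True,
) -> tuple[VariationalState, Projection]:
    """Run coordinate ascent to convergence and project the data.

    Parameters
    ----------
    X : ndarray (m_features, n_samples)
        Feature-major data matrix.
    c : ndarray (n_samples,)
        Pseudo-labels in 1..K, every class occupied.
    hyper : Hyperparams
        Gamma hyperparameters, projection dimension and controls.
    standardize : bool
        Z-score each feature before inference (default).  The fitted
        scaler is stored on the returned Projection for reuse.

    Returns
    -------
    (VariationalState, Projection)
        Final posterior state and the projection U = Xᵀ E[Q] (of the
        standardized X when standardization is on).
    """
    hyper = hyper or Hyperparams()
    X = np.asarray(X, dtype=float)
    c = np.asarray(c, dtype=int)
    feat_mean = feat_std = None
    if standardize:
        X, feat_mean, feat_std = _standardize(X)
    if not np.isfinite(X).all():
        raise ProjectionError("non-finite values in feature matrix X")
    state = init_state(X, c, hyper)
    mu_prev = state.mu_Q.copy()
    for _ in range(hyper.max_iter):
        update_phi(state, hyper)
        update_Q(state, X)
        update_Z(state, X)
        update_priors_and_bW(state, hyper)
        update_T(state, c, hyper)
        denom = max(np.abs(state.mu_Q).max(), 1e-12)
        delta = np.abs(state.mu_Q - mu_prev).max() / denom
        mu_prev = state.mu_Q.copy()
        if delta < hyper.tol:
            break
    proj = Projection(
        mu_Q=state.mu_Q.copy(),
        U=X.T @ state.mu_Q,
        feature_mean=feat_mean,
        feature_std=feat_std,
    )
    return state, proj


def transform(X_new: np.ndarray, proj: Projection | np.ndarray) -> np.ndarray:
    """Project new feature-major data with a fitted mu_Q: U_new = X_newᵀ mu_Q."""
    if isinstance(proj, Projection):
        mu_Q = proj.mu_Q
        X_new = np.asarray(X_new, dtype=float)
        if proj.feature_mean is not None:
            X_new = (X_new - proj.feature_mean[:, None]) / proj.feature_std[:, None]
    else:
        mu_Q = np.asarray(proj)
        X_new = np.asarray(X_new, dtype=float)
    if X_new.shape[0] != mu_Q.shape[0]:
        raise ProjectionError(
            f"feature dimension mismatch: X_new has {X_new.shape[0]} features, "
            f"mu_Q expects {mu_Q.shape[0]}"
        )
    return X_new.T @ mu_Q
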