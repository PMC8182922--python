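"""Penalised maximum-likelihood logistic / multinomial fits with posterior draws.

These are the inner fits of the chained-equations imputation engine.  Each
imputation step refits a working model on the currently-completed data, draws a
coefficient vector from the large-sample normal approximation of its posterior
(mean = MLE, covariance = inverse observed information), and imputes from that
draw.  The engine performs thousands of such refits per run, so the solvers are
plain Newton–Raphson on numpy arrays with an optional ridge penalty used to
stabilise separated or collinear fits.

Coefficient estimates and covariances agree with statsmodels' ``Logit`` on
well-behaved data (checked in the test-suite); the local implementation exists
so the posterior-draw + offset machinery stays self-contained and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

#: ridge penalty applied when a plain ML fit separates or is singular
RIDGE_FALLBACK = 1e-4


class SeparationError(RuntimeError):
    """Raised internally when an unpenalised fit diverges."""


@dataclass
class GlmFit:
    """A fitted (possibly ridge-penalised) GLM.

    ``params`` is the coefficient vector (multinomial: shape (K-1)*p, level-major),
    ``cov`` its approximate posterior covariance (inverse penalised information).
    """

    params: np.ndarray
    cov: np.ndarray
    converged: bool
    ridge: float = 0.0
    separation: bool = False
    kept_columns: np.ndarray | None = field(default=None, repr=False)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One draw from N(params, cov); jitters the factorisation if needed."""
        try:
            chol = np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError:
            jitter = 1e-10 * (1.0 + np.abs(np.diag(self.cov)).max())
            chol = np.linalg.cholesky(self.cov + jitter * np.eye(len(self.params)))
        return self.params + chol @ rng.standard_normal(len(self.params))


def prune_constant_columns(X: np.ndarray) -> np.ndarray:
    """Indices of columns to keep: column 0 (intercept) plus all non-constant ones.

    A predictor that is constant over the fitting rows carries no information and
    — crucially for imputation — may take *different* values on the rows being
    predicted (e.g. the follow-up flag when the outcome is only observed for
    responders), so it must be removed from both fit and prediction.
    """
    keep = [0]
    for j in range(1, X.shape[1]):
        col = X[:, j]
        if col.max() - col.min() > 1e-12:
            keep.append(j)
    return np.asarray(keep, dtype=np.intp)


def _newton_logistic(X, y, ridge, max_iter=60, tol=1e-9, start=None):
    n, p = X.shape
    if start is not None and len(start) == p:
        beta = np.asarray(start, dtype=float).copy()
    else:
        beta = np.zeros(p)
        # start the intercept at the empirical logit for faster convergence
        ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
        beta[0] = np.log(ybar / (1 - ybar))
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - ridge * beta
        H = (X * w[:, None]).T @ X + ridge * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix") from exc
        beta = beta + step
        if np.abs(step).max() < 1e-8:
            converged = True
            break
    if not converged or np.abs(beta).max() > 30.0:
        raise SeparationError("logistic fit diverged")
    return beta, np.linalg.inv(H), converged


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0,
                 start: np.ndarray | None = None) -> GlmFit:
    """ML logistic fit of ``y`` (0/1) on ``X`` (first column = intercept).

    A plain ML fit is attempted first (optionally warm-started); on
    (quasi-)separation or a singular information matrix the fit is repeated
    with a small ridge penalty (``RIDGE_FALLBACK``) and flagged via
    ``separation``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    try:
        beta, cov, conv = _newton_logistic(X, y, ridge, start=start)
        return GlmFit(beta, cov, conv, ridge=ridge)
    except SeparationError:
        beta, cov, conv = _newton_logistic(X, y, max(ridge, RIDGE_FALLBACK), max_iter=200)
        return GlmFit(beta, cov, conv, ridge=max(ridge, RIDGE_FALLBACK), separation=True)


def _softmax_probs(X, B):
    # B: p x (K-1); implicit baseline level 0 with linear predictor 0
    eta = X @ B
    eta = np.concatenate([np.zeros((X.shape[0], 1)), eta], axis=1)
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def _newton_multinomial(X, y, K, ridge, max_iter=80, start=None):
    n, p = X.shape
    if start is not None and len(start) == p * (K - 1):
        B = np.asarray(start, dtype=float).reshape(K - 1, p).T.copy()
    else:
        B = np.zeros((p, K - 1))
    H = np.eye(p * (K - 1))
    converged = False
    Y = np.zeros((n, K))
    Y[np.arange(n), y] = 1.0
    for _ in range(max_iter):
        P = _softmax_probs(X, B)
        grad = (X.T @ (Y[:, 1:] - P[:, 1:])).T.ravel() - ridge * B.T.ravel()
        # Hessian blocks H[a,b] = X' diag(p_a (1{a=b} - p_b)) X for a,b in 1..K-1
        H = np.empty((p * (K - 1), p * (K - 1)))
        for a in range(1, K):
            for b in range(1, K):
                w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
                if a == b:
                    w = P[:, a] * (1.0 - P[:, a])
                else:
                    w = -P[:, a] * P[:, b]
                block = (X * w[:, None]).T @ X
                H[(a - 1) * p:a * p, (b - 1) * p:b * p] = block
        H += ridge * np.eye(p * (K - 1))
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular multinomial information") from exc
        B = B + step.reshape(K - 1, p).T
        if np.abs(step).max() < 1e-8:
            converged = True
            break
    if not converged or np.abs(B).max() > 30.0:
        raise SeparationError("multinomial fit diverged")
    return B, np.linalg.inv(H), converged


def fit_multinomial(X: np.ndarray, y: np.ndarray, n_levels: int, ridge: float = 0.0,
                    start: np.ndarray | None = None) -> GlmFit:
    """ML multinomial-logit fit of integer codes ``y`` in 0..n_levels-1 on ``X``.

    Level 0 is the reference.  ``params`` is the flattened (level-major)
    coefficient array of shape (n_levels-1)*p.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.intp)
    try:
        B, cov, conv = _newton_multinomial(X, y, n_levels, ridge, start=start)
        return GlmFit(B.T.ravel(), cov, conv, ridge=ridge)
    except SeparationError:
        B, cov, conv = _newton_multinomial(X, y, n_levels, max(ridge, RIDGE_FALLBACK), max_iter=300)
        return GlmFit(B.T.ravel(), cov, conv, ridge=max(ridge, RIDGE_FALLBACK), separation=True)


def multinomial_probs(X: np.ndarray, params: np.ndarray, n_levels: int) -> np.ndarray:
    """Level probabilities for a flattened multinomial coefficient vector."""
    p = X.shape[1]
    B = params.reshape(n_levels - 1, p).T
    return _softmax_probs(np.asarray(X, dtype=float), B)


def fit_linear(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8):
    """OLS fit returning (beta, XtX_inv, sigma2_hat, df) for Bayesian PMM draws."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / df
    return beta, XtX_inv, sigma2, df
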