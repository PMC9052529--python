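"""Huber robust linear regression, vectorized over many response vectors.

An epigenome-wide scan fits the same design matrix to every CpG, so the
IRLS loop here operates on a whole response matrix at once: per-column
Huber weights, batched weighted least squares, and the standard robust
asymptotic (sandwich-with-correction, "H1") covariance. A single response
vector goes through the same code path.

Conventions (matching the common robust-regression defaults): Huber tuning
constant c = 1.345, scale = MAD of residuals about zero re-estimated each
iteration, convergence when the largest coefficient change is below tol,
p-values from the t distribution with n - rank(X) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

HUBER_C = 1.345
#: Phi^{-1}(3/4): scales the MAD to be consistent for a normal sigma.
_MAD_K = 0.6744897501960817


@dataclass
class HuberFit:
    """Result of a (possibly batched) Huber IRLS fit.

    Arrays are (p, m): one column per response vector. ``converged`` flags
    columns whose coefficients stabilised within ``max_iter`` iterations;
    for the rest the last iterate is returned.
    """

    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    scale: np.ndarray
    converged: np.ndarray
    df_resid: int


def _mad_scale(resid: np.ndarray) -> np.ndarray:
    """Median absolute residual about zero, normal-consistent."""
    return np.median(np.abs(resid), axis=0) / _MAD_K


def huber_fit_matrix(
    X: np.ndarray,
    Y: np.ndarray,
    c: float = HUBER_C,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> HuberFit:
    """Fit Y[:, j] ~ X for every column j by Huber IRLS.

    Parameters
    ----------
    X : (n, p) design matrix (include the intercept column explicitly).
    Y : (n,) or (n, m) response(s).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    m = Y.shape[1]
    if Y.shape[0] != n:
        raise ValueError("X and Y have incompatible numbers of rows")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("singular design matrix (rank %d < %d columns)" % (rank, p))
    if n <= p:
        raise ValueError("need more observations than design columns")

    xtx_inv = np.linalg.inv(X.T @ X)
    # G[i] = outer(X[i], X[i]) flattened; lets XtWX come out of one matmul.
    G = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)

    B = (np.linalg.pinv(X) @ Y)  # OLS start, (p, m)
    converged = np.zeros(m, dtype=bool)
    scale = np.empty(m)
    active = np.arange(m)
    for _ in range(max_iter):
        R = Y[:, active] - X @ B[:, active]
        s = _mad_scale(R)
        exact = s < 1e-10  # perfect fits: nothing for IRLS to do
        s = np.where(exact, 1.0, s)
        U = R / s
        W = np.minimum(1.0, c / np.maximum(np.abs(U), 1e-300))
        XtWX = (W.T @ G).reshape(-1, p, p)
        XtWY = np.einsum("ip,ij->jp", X, W * Y[:, active])
        B_new = np.linalg.solve(XtWX, XtWY[..., None])[..., 0].T
        delta = np.max(np.abs(B_new - B[:, active]), axis=0)
        B[:, active] = B_new
        done = (delta < tol) | exact
        scale[active] = np.where(exact, 0.0, s)
        converged[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    if active.size:
        R = Y[:, active] - X @ B[:, active]
        scale[active] = _mad_scale(R)

    # H1 covariance: k^2 * [sum psi(u)^2 / (n-p)] * s^2 / mean(psi')^2 * (X'X)^-1
    R = Y - X @ B
    s_safe = np.where(scale < 1e-10, 1.0, scale)
    U = R / s_safe
    psi = np.clip(U, -c, c)
    psi_deriv = (np.abs(U) <= c).astype(float)
    mpd = psi_deriv.mean(axis=0)
    mpd = np.where(mpd == 0, np.nan, mpd)
    var_pd = psi_deriv.var(axis=0)
    k = 1.0 + (p / n) * var_pd / mpd**2
    df_resid = n - p
    ssq = (psi**2).sum(axis=0) / df_resid
    factor = k**2 * ssq * scale**2 / mpd**2
    se = np.sqrt(np.outer(np.diag(xtx_inv), factor))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = B / se
    pvalues = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    return HuberFit(
        coef=B, se=se, pvalues=pvalues, scale=scale, converged=converged,
        df_resid=df_resid,
    )


def huber_rlm(y: np.ndarray, X: np.ndarray, **kwargs):
    """Huber M-regression of a single response vector.

    Returns (coefficients, robust SEs, p-values); the full fit object is
    available via :func:`huber_fit_matrix`.
    """
    fit = huber_fit_matrix(X, np.asarray(y, dtype=float), **kwargs)
    return fit.coef[:, 0], fit.se[:, 0], fit.pvalues[:, 0]
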