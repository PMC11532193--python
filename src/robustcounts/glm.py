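"""Poisson log-linear regression fitted by iteratively reweighted least squares.

The mean model is ``E[y_i] = mu_i = exp(o_i + x_i' beta)`` with a log link and
an optional log-scale offset ``o_i`` (e.g. log library size, i.e. total-sum
scaling).  The Poisson quasi-score ``X' (y - mu) = 0`` identifies ``beta``
whenever the mean model is correct, even if the response is continuous or its
variance is not Poisson; the point estimate is therefore shared by every
variance estimator in :mod:`robustcounts.covariance`.

Fisher scoring for the canonical log link updates

    beta_{k+1} = beta_k + (X' W_k X)^{-1} X' (y - mu_k),   W_k = diag(mu_k),

starting from an intercept-only model (intercept = log of the mean response,
all other coefficients zero) and stopping when the Euclidean norm of the beta
update drops below ``tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DesignResponse", "PoissonFit", "irls_fit", "hat_diagonals"]

# exp() overflow guard on the linear predictor; never binding at a solution
# for sane data, only during early Fisher-scoring steps.
_ETA_MAX = 500.0


@dataclass
class DesignResponse:
    """A single regression problem: response, design matrix, optional offset.

    Parameters
    ----------
    y : array-like of shape (n,)
        Non-negative response.  Continuous values are allowed: the Poisson
        quasi-score is well defined for any real ``y >= 0``.
    X : array-like of shape (n, p)
        Design matrix including the intercept column.  Must have full column
        rank.
    offset : array-like of shape (n,), optional
        Log-scale offset; defaults to zero.
    """

    y: np.ndarray
    X: np.ndarray
    offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if self.X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("y and X disagree on the number of samples")
        if not (n >= p >= 1):
            raise ValueError(f"need n >= p >= 1, got n={n}, p={p}")
        if not np.all(np.isfinite(self.y)) or np.any(self.y < 0):
            raise ValueError("y must be finite and non-negative")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X must be finite")
        if self.offset is None:
            self.offset = np.zeros(n)
        else:
            self.offset = np.asarray(self.offset, dtype=float)
            if self.offset.shape != (n,):
                raise ValueError("offset must have shape (n,)")
            if not np.all(np.isfinite(self.offset)):
                raise ValueError("offset must be finite")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("X is rank deficient (collinear columns)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class PoissonFit:
    """Converged state of one IRLS fit.

    Attributes
    ----------
    beta : (p,) coefficients on the log scale.
    mu : (n,) fitted means ``exp(offset + X beta)``.
    weights : (n,) IRLS weights, equal to ``mu`` for the log link.
    leverages : (n,) diagonal of the hat matrix ``X (X'WX)^{-1} X' W``.
    residuals : (n,) response residuals ``y - mu``.
    converged : whether the update norm dropped below ``tol_used``.
    n_iter : Fisher-scoring iterations performed.
    tol_used : convergence tolerance on the Euclidean norm of the update.
    """

    beta: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    leverages: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int
    tol_used: float
    meta: dict = field(default_factory=dict)


def _hat_diag(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Diagonal of X (X'WX)^{-1} X' W for diagonal weights w."""
    XtWX = (X * w[:, None]).T @ X
    try:
        A = np.linalg.solve(XtWX, X.T)  # (p, n)
    except np.linalg.LinAlgError as exc:
        raise ValueError("X'WX is singular (rank-deficient weighted design)") from exc
    return np.einsum("ij,ji->i", X, A) * w


def irls_fit(
    data: DesignResponse,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> PoissonFit:
    """Fit the Poisson log-linear model by Fisher scoring.

    Parameters
    ----------
    data : DesignResponse
    tol : float
        Convergence tolerance on ``||beta_{k+1} - beta_k||_2``.
    max_iter : int
        Maximum Fisher-scoring iterations.  On non-convergence the last
        iterate is returned with ``converged=False`` and a warning.

    Returns
    -------
    PoissonFit

    Raises
    ------
    ValueError
        If the response is identically zero (the intercept initialisation,
        the log of the mean response, is undefined) or the weighted
        cross-product matrix is singular.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    y, X, offset = data.y, data.X, data.offset
    n, p = X.shape
    ybar = y.mean()
    if ybar <= 0:
        raise ValueError(
            "response is identically zero: log of the mean response is "
            "undefined; filter such responses upstream"
        )

    beta = np.zeros(p)
    # Intercept-only start: log mean response (offset-adjusted when offsets
    # are present; reduces to log(mean(y)) for zero offset).
    col0 = X[:, 0]
    if np.ptp(col0) == 0 and col0[0] != 0:
        beta[0] = (np.log(ybar) - offset.mean()) / col0[0]

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        score = X.T @ (y - mu)
        XtWX = (X * mu[:, None]).T @ X
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular weighted cross-product matrix X'WX"
            ) from exc
        beta = beta + delta
        if np.linalg.norm(delta) < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations", RuntimeWarning
        )

    eta = np.clip(offset + X @ beta, -_ETA_MAX, _ETA_MAX)
    mu = np.exp(eta)
    return PoissonFit(
        beta=beta,
        mu=mu,
        weights=mu,
        leverages=_hat_diag(X, mu),
        residuals=y - mu,
        converged=converged,
        n_iter=n_iter,
        tol_used=tol,
    )


def hat_diagonals(fit: PoissonFit, X: np.ndarray) -> np.ndarray:
    """Leverages: diagonal of the GLM hat matrix ``X (X'WX)^{-1} X' W``.

    Evaluated at the fit's converged weights.  The diagonal coincides with
    that of the symmetric form ``W^{1/2} X (X'WX)^{-1} X' W^{1/2}``, so every
    value lies in (0, 1) and the trace equals p.
    """
    X = np.asarray(X, dtype=float)
    return _hat_diag(X, fit.weights)


def _irls_batch(
    yb: np.ndarray,
    Xb: np.ndarray,
    ob: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Fisher scoring across a batch of B small problems.

    Parameters
    ----------
    yb : (B, n) responses, each with positive mean.
    Xb : (B, n, p) design matrices, each full column rank.
    ob : (B, n) offsets.

    Returns
    -------
    betas : (B, p)
    ok : (B,) boolean, True where the update norm fell below tol.

    Used by the case-resampling bootstrap, where refitting B ~ 1000 small
    regressions one by one would dominate the run time.
    """
    B, n, p = Xb.shape
    beta = np.zeros((B, p))
    ybar = yb.mean(axis=1)
    col0 = Xb[:, :, 0]
    const0 = (np.ptp(col0, axis=1) == 0) & (col0[:, 0] != 0)
    beta[const0, 0] = (np.log(ybar[const0]) - ob[const0].mean(axis=1)) / col0[
        const0, 0
    ]

    ok = np.zeros(B, dtype=bool)
    active = np.arange(B)
    for _ in range(max_iter):
        Xa, ya, oa, ba = Xb[active], yb[active], ob[active], beta[active]
        eta = np.clip(oa + np.einsum("bnp,bp->bn", Xa, ba), -_ETA_MAX, _ETA_MAX)
        mu = np.exp(eta)
        score = np.einsum("bnp,bn->bp", Xa, ya - mu)
        info = np.einsum("bnp,bn,bnq->bpq", Xa, mu, Xa)
        delta = np.linalg.solve(info, score[..., None])[..., 0]
        beta[active] = ba + delta
        done = np.linalg.norm(delta, axis=1) < tol
        ok[active[done]] = True
        active = active[~done]
        if active.size == 0:
            break
    return beta, ok
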