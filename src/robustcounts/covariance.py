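"""Covariance estimators for the Poisson log-linear coefficient vector.

Five estimators of Cov(beta_hat) sharing one point estimate:

``poisson_naive``
    Model-based inverse information ``(X'WX)^{-1}``.  Correct only when the
    response is genuinely Poisson; under- or over-states uncertainty when the
    mean-variance law is misspecified.
``sandwich_hc3``
    Heteroscedasticity-consistent sandwich with the HC3 small-sample leverage
    adjustment: bread ``(X'WX)^{-1}``, meat
    ``X' diag((e_i / (1 - h_ii))^2) X`` with response residuals
    ``e = y - mu`` and hat-diagonal leverages ``h_ii``.
``bootstrap``
    Empirical covariance of the coefficients over B case resamples (rows of
    (y, X, offset) drawn jointly with replacement) refit by IRLS.
``quasipoisson``
    Model-based covariance scaled by the Pearson dispersion estimate
    ``phi_hat = sum(e_i^2 / mu_i) / (n - p)`` (variance law V = phi * mu).
``negbin``
    Inverse expected information of an NB2 maximum-likelihood fit
    (V = mu + mu^2 / r), the classical parametric treatment of
    overdispersion, included as a baseline.

The sandwich and bootstrap estimators are consistent for the true sampling
variance whenever the log-linear mean is correct, regardless of the variance
law — which is exactly the regime of microbiome abundance counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .glm import DesignResponse, PoissonFit, _hat_diag, _irls_batch, irls_fit

__all__ = [
    "CovarianceResult",
    "poisson_naive_cov",
    "hc3_sandwich_cov",
    "bootstrap_cov",
    "quasipoisson_cov",
    "negbin_fit_cov",
    "METHODS",
]

METHODS = ("poisson_naive", "sandwich_hc3", "bootstrap", "negbin", "quasipoisson")

# NB size above which the fit is declared equidispersed (Poisson boundary).
_NB_SIZE_CEILING = 1e7


@dataclass
class CovarianceResult:
    """A p x p coefficient covariance tagged by the estimator that made it."""

    method: str
    cov: np.ndarray
    se: np.ndarray = field(init=False)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        self.cov = 0.5 * (self.cov + self.cov.T)  # enforce exact symmetry
        diag = np.diag(self.cov)
        if np.any(diag < -1e-12):
            raise ValueError("covariance has negative diagonal entries")
        self.se = np.sqrt(np.clip(diag, 0.0, None))


def _bread(fit: PoissonFit, X: np.ndarray) -> np.ndarray:
    XtWX = (X * fit.weights[:, None]).T @ X
    try:
        return np.linalg.inv(XtWX)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular information matrix X'WX") from exc


def poisson_naive_cov(fit: PoissonFit, X: np.ndarray) -> CovarianceResult:
    """Model-based Poisson covariance ``(X'WX)^{-1}`` at the converged weights."""
    X = np.asarray(X, dtype=float)
    return CovarianceResult(method="poisson_naive", cov=_bread(fit, X))


def _sandwich(fit: PoissonFit, X: np.ndarray, adjust: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    e = fit.residuals
    if adjust == "hc3":
        h = fit.leverages
        bad = np.flatnonzero(h >= 1 - 1e-12)
        if bad.size:
            raise ValueError(
                f"leverage h_ii = 1 at sample index {bad[0]}: HC3 scaling "
                "1/(1-h_ii) is undefined (perfect-leverage point)"
            )
        u = e / (1.0 - h)
    elif adjust == "hc0":
        u = e
    else:  # pragma: no cover - internal guard
        raise ValueError(f"unknown adjustment {adjust!r}")
    bread = _bread(fit, X)
    meat = (X * (u**2)[:, None]).T @ X
    return bread @ meat @ bread


def hc3_sandwich_cov(fit: PoissonFit, X: np.ndarray) -> CovarianceResult:
    """HC3 sandwich covariance.

    ``(X'WX)^{-1} X' diag((e_i/(1-h_ii))^2) X (X'WX)^{-1}`` with response
    residuals ``e = y - exp(X beta_hat)`` and leverages from the GLM hat
    matrix.  The 1/(1-h_ii) inflation makes the estimator nearly unbiased in
    small samples, the recommended variant for modest-n studies.
    """
    return CovarianceResult(method="sandwich_hc3", cov=_sandwich(fit, X, "hc3"))


def bootstrap_cov(
    data: DesignResponse,
    B: int = 1000,
    seed=None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CovarianceResult:
    """Case-resampling bootstrap covariance of the IRLS coefficients.

    Rows of ``(y, X, offset)`` are resampled jointly with replacement (size
    n), the Poisson model is refit on each resample, and the empirical
    covariance of the B coefficient vectors (denominator B-1) is returned.

    Resamples on which the design degenerates (a covariate collapsing to one
    level, or an all-zero response) are redrawn and counted in
    ``meta["n_redrawn"]``; if degenerate draws ever exceed 10% of B the data
    are deemed too fragile to bootstrap and a ``RuntimeError`` is raised.

    Deterministic given ``seed`` (any value accepted by
    ``numpy.random.default_rng``).
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    y, X, offset = data.y, data.X, data.offset
    n, p = X.shape

    idx = np.empty((B, n), dtype=np.intp)
    needed = B
    filled = 0
    n_redrawn = 0
    while needed > 0:
        cand = rng.integers(0, n, size=(needed, n))
        Xc = X[cand]  # (needed, n, p)
        gram = np.einsum("bnp,bnq->bpq", Xc, Xc)
        ev = np.linalg.eigvalsh(gram)
        full_rank = ev[:, 0] > 1e-10 * np.maximum(ev[:, -1], 1.0)
        nonzero_y = y[cand].mean(axis=1) > 0
        good = full_rank & nonzero_y
        n_bad = int(needed - good.sum())
        n_redrawn += n_bad
        if n_redrawn > 0.1 * B:
            raise RuntimeError(
                f"{n_redrawn} degenerate bootstrap resamples (> 10% of B={B}); "
                "design too fragile for case resampling"
            )
        take = cand[good]
        idx[filled : filled + take.shape[0]] = take
        filled += take.shape[0]
        needed -= take.shape[0]

    betas, ok = _irls_batch(y[idx], X[idx], offset[idx], tol=tol, max_iter=max_iter)
    if not np.all(ok):
        warnings.warn(
            f"{int((~ok).sum())} of {B} bootstrap refits did not converge; "
            "they are retained at the last iterate",
            RuntimeWarning,
        )
    cov = np.cov(betas, rowvar=False, ddof=1)
    return CovarianceResult(
        method="bootstrap",
        cov=np.atleast_2d(cov),
        meta={"B": B, "seed": seed, "n_redrawn": n_redrawn},
    )


def quasipoisson_cov(fit: PoissonFit, X: np.ndarray) -> CovarianceResult:
    """Quasi-Poisson covariance: Pearson-dispersion-scaled inverse information.

    ``phi_hat = sum((y_i - mu_i)^2 / mu_i) / (n - p)``;
    ``cov = phi_hat * (X'WX)^{-1}``.  Wald inference conventionally refers the
    statistic to a t distribution with n - p degrees of freedom
    (``meta["df"]``).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("dispersion undefined: need n > p")
    phi = float(np.sum(fit.residuals**2 / fit.mu) / (n - p))
    return CovarianceResult(
        method="quasipoisson",
        cov=phi * _bread(fit, X),
        meta={"dispersion": phi, "df": n - p},
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, r: float) -> float:
    """NB2 log-likelihood with mean mu and size r (Var = mu + mu^2/r).

    For non-integer y this is the same expression evaluated at real y
    (a quasi-likelihood); gammaln(y+1) generalises the factorial.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
        t = np.where((y == 0) & (mu == 0), r * np.log(r / (r + mu)), t)
    return float(np.sum(t))


def _nb_irls_beta(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    r: float,
    beta: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, bool]:
    """Fisher scoring for beta in the NB2 model at fixed size r."""
    for _ in range(max_iter):
        mu = np.exp(np.clip(offset + X @ beta, -500, 500))
        w = mu / (1.0 + mu / r)
        score = X.T @ ((y - mu) / (1.0 + mu / r))
        info = (X * w[:, None]).T @ X
        delta = np.linalg.solve(info, score)
        beta = beta + delta
        if np.linalg.norm(delta) < tol:
            return beta, True
    return beta, False


def negbin_fit_cov(
    data: DesignResponse,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[PoissonFit, CovarianceResult]:
    """NB2 maximum-likelihood fit and its model-based coefficient covariance.

    Alternates Fisher scoring for beta (at fixed size r) with a 1-D profile
    likelihood maximisation over log r, from a Poisson start and a
    method-of-moments r.  The covariance is the inverse expected information
    for beta at (beta_hat, r_hat), i.e. ``(X' diag(mu/(1+mu/r)) X)^{-1}``.

    Non-integer responses are accepted with a warning (the Gamma-function
    form of the log-likelihood is a valid quasi-likelihood at real y >= 0).
    If r_hat runs to the equidispersion boundary the Poisson covariance is
    returned with a warning.
    """
    y, X, offset = data.y, data.X, data.offset
    n, p = X.shape
    if np.any(y != np.floor(y)):
        warnings.warn(
            "non-integer response: NB log-likelihood evaluated at real y "
            "(quasi-likelihood)",
            RuntimeWarning,
        )

    pois = irls_fit(data, tol=tol, max_iter=50)
    beta = pois.beta.copy()
    mu = pois.mu
    # method-of-moments start for the size
    excess = np.mean((y - mu) ** 2 - mu)
    m2 = np.mean(mu**2)
    r = m2 / excess if excess > 0 else _NB_SIZE_CEILING
    r = float(np.clip(r, 1e-3, _NB_SIZE_CEILING))

    converged = False
    n_outer = 0
    for n_outer in range(1, max_iter + 1):
        beta_new, _ = _nb_irls_beta(y, X, offset, r, beta, tol, 50)
        mu = np.exp(np.clip(offset + X @ beta_new, -500, 500))
        res = minimize_scalar(
            lambda lr: -_nb_loglik(y, mu, np.exp(lr)),
            bounds=(np.log(1e-4), np.log(_NB_SIZE_CEILING)),
            method="bounded",
            options={"xatol": 1e-10},
        )
        r_new = float(np.exp(res.x))
        step = np.linalg.norm(beta_new - beta) + abs(np.log(r_new) - np.log(r))
        beta, r = beta_new, r_new
        if step < max(tol, 1e-9):
            converged = True
            break
    if not converged:
        warnings.warn("NB fit did not converge", RuntimeWarning)

    mu = np.exp(np.clip(offset + X @ beta, -500, 500))
    w = mu / (1.0 + mu / r)
    fit = PoissonFit(
        beta=beta,
        mu=mu,
        weights=w,
        leverages=_hat_diag(X, w),
        residuals=y - mu,
        converged=converged,
        n_iter=n_outer,
        tol_used=tol,
        meta={"size": r, "loglik": _nb_loglik(y, mu, r)},
    )
    if r >= _NB_SIZE_CEILING * 0.99:
        warnings.warn(
            "NB size at the equidispersion boundary; returning the Poisson "
            "covariance",
            RuntimeWarning,
        )
        cov = _bread(pois, X)
    else:
        cov = np.linalg.inv((X * w[:, None]).T @ X)
    return fit, CovarianceResult(method="negbin", cov=cov, meta={"size": r})
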