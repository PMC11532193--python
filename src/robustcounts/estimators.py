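"""scikit-learn-style estimators wrapping the IRLS core.

``PoissonRegression`` is the package's front door: a log-linear count
regression whose point estimate is the Poisson MLE and whose uncertainty
comes from a selectable covariance estimator (HC3 sandwich by default).  It
composes with sklearn pipelines and model selection; the functional API in
:mod:`robustcounts.glm` / :mod:`robustcounts.covariance` exposes the same
computations on raw design matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from . import covariance as cov_mod
from .glm import DesignResponse, irls_fit
from .inference import wald_test

__all__ = ["PoissonRegression", "NegativeBinomialRegression"]


def _design(X: np.ndarray, fit_intercept: bool) -> np.ndarray:
    if fit_intercept:
        return np.column_stack([np.ones(X.shape[0]), X])
    return np.asarray(X, dtype=float)


class PoissonRegression(RegressorMixin, BaseEstimator):
    """Poisson log-linear regression with robust standard errors.

    Parameters
    ----------
    cov_type : {"hc3", "bootstrap", "naive", "quasipoisson"}, default "hc3"
        Covariance estimator for the coefficients.  "hc3" (the
        leverage-adjusted sandwich) and "bootstrap" (case resampling) are
        consistent under arbitrary mean-variance laws; "naive" is the
        model-based Poisson covariance; "quasipoisson" scales it by the
        Pearson dispersion.
    fit_intercept : bool, default True
        Prepend a constant column to X.
    tol, max_iter : IRLS stopping rule (Euclidean norm of the update).
    bootstrap_B : int, default 1000
        Number of case resamples when ``cov_type="bootstrap"``.
    random_state : seed for the bootstrap resampler.
    ci_level : confidence level for ``summary`` intervals.

    Attributes
    ----------
    coef_ : (n_features,) slope coefficients on the log scale.
    intercept_ : float, 0.0 when ``fit_intercept=False``.
    cov_params_ : (p, p) coefficient covariance in [intercept, features] order.
    bse_ : (p,) standard errors, same order.
    mu_, leverages_, converged_, n_iter_ : fit diagnostics.
    dispersion_ : Pearson dispersion (quasi-Poisson only).
    """

    _cov_types = ("hc3", "bootstrap", "naive", "quasipoisson")

    def __init__(
        self,
        cov_type: str = "hc3",
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_iter: int = 50,
        bootstrap_B: int = 1000,
        random_state=None,
        ci_level: float = 0.95,
    ):
        self.cov_type = cov_type
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.bootstrap_B = bootstrap_B
        self.random_state = random_state
        self.ci_level = ci_level

    def fit(self, X, y, offset=None):
        if self.cov_type not in self._cov_types:
            raise ValueError(
                f"cov_type must be one of {self._cov_types}, got {self.cov_type!r}"
            )
        X, y = check_X_y(X, y, y_numeric=True)
        Xd = _design(X, self.fit_intercept)
        data = DesignResponse(y, Xd, offset=offset)
        fit = irls_fit(data, tol=self.tol, max_iter=self.max_iter)

        if self.cov_type == "naive":
            res = cov_mod.poisson_naive_cov(fit, Xd)
        elif self.cov_type == "hc3":
            res = cov_mod.hc3_sandwich_cov(fit, Xd)
        elif self.cov_type == "quasipoisson":
            res = cov_mod.quasipoisson_cov(fit, Xd)
        else:
            res = cov_mod.bootstrap_cov(
                data,
                B=self.bootstrap_B,
                seed=self.random_state,
                tol=self.tol,
                max_iter=self.max_iter,
            )

        self.n_features_in_ = X.shape[1]
        if self.fit_intercept:
            self.intercept_ = float(fit.beta[0])
            self.coef_ = fit.beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = fit.beta.copy()
        self.cov_params_ = res.cov
        self.bse_ = res.se
        self.mu_ = fit.mu
        self.leverages_ = fit.leverages
        self.converged_ = fit.converged
        self.n_iter_ = fit.n_iter
        if self.cov_type == "quasipoisson":
            self.dispersion_ = res.meta["dispersion"]
        self.result_ = fit
        self.cov_result_ = res
        return self

    def predict(self, X, offset=None):
        """Expected counts ``exp(offset + intercept + X @ coef_)``."""
        check_is_fitted(self, "coef_")
        X = check_array(X)
        eta = self.intercept_ + X @ self.coef_
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)

    def summary(self) -> pd.DataFrame:
        """Per-coefficient Wald table: estimate, se, statistic, p, CI."""
        check_is_fitted(self, "coef_")
        beta = np.concatenate([[self.intercept_], self.coef_]) if self.fit_intercept else self.coef_
        ref, df = "normal", None
        if self.cov_type == "quasipoisson":
            ref, df = "t", self.cov_result_.meta["df"]
        rows = []
        for b, s in zip(np.atleast_1d(beta), self.bse_):
            w = wald_test(b, s, level=self.ci_level, reference_dist=ref, df=df)
            rows.append(
                {
                    "estimate": w.estimate,
                    "se": w.se,
                    "statistic": w.statistic,
                    "p_value": w.p_value,
                    "ci_lower": w.ci_lower,
                    "ci_upper": w.ci_upper,
                }
            )
        names = (
            ["intercept"] + [f"x{i}" for i in range(len(self.coef_))]
            if self.fit_intercept
            else [f"x{i}" for i in range(len(self.coef_))]
        )
        return pd.DataFrame(rows, index=names)


class NegativeBinomialRegression(RegressorMixin, BaseEstimator):
    """NB2 log-linear regression (Var = mu + mu^2 / size), the parametric
    overdispersion baseline.

    Attributes mirror :class:`PoissonRegression`, plus ``size_`` for the
    estimated NB size (inverse dispersion) parameter.
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-8, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, offset=None):
        X, y = check_X_y(X, y, y_numeric=True)
        Xd = _design(X, self.fit_intercept)
        data = DesignResponse(y, Xd, offset=offset)
        fit, res = cov_mod.negbin_fit_cov(data, tol=self.tol, max_iter=self.max_iter)
        self.n_features_in_ = X.shape[1]
        if self.fit_intercept:
            self.intercept_ = float(fit.beta[0])
            self.coef_ = fit.beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = fit.beta.copy()
        self.size_ = res.meta["size"]
        self.cov_params_ = res.cov
        self.bse_ = res.se
        self.converged_ = fit.converged
        self.result_ = fit
        self.cov_result_ = res
        return self

    def predict(self, X, offset=None):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        eta = self.intercept_ + X @ self.coef_
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return np.exp(eta)
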