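"""Wald tests, confidence intervals, and multiplicity adjustment."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["WaldResult", "wald_test", "bh_adjust"]


@dataclass
class WaldResult:
    """Two-sided Wald test of a single coefficient against zero.

    ``statistic = estimate / se`` is referred to the standard normal or, for
    dispersion-estimated covariances (quasi-Poisson), to a t distribution
    with the residual degrees of freedom.  The confidence interval is the
    symmetric Wald interval ``estimate +/- q * se``.
    """

    estimate: float
    se: float
    statistic: float
    p_value: float
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    reference_dist: str = "normal"


def wald_test(
    estimate: float,
    se: float,
    level: float = 0.95,
    reference_dist: str = "normal",
    df: int | None = None,
) -> WaldResult:
    """Two-sided Wald test and symmetric confidence interval.

    Parameters
    ----------
    estimate, se : point estimate and its standard error (se > 0).
    level : confidence level, default 0.95.
    reference_dist : "normal" or "t"; "t" requires ``df``.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = estimate / se
    if reference_dist == "normal":
        p = 2.0 * stats.norm.sf(abs(z))
        q = stats.norm.ppf(1 - (1 - level) / 2)
        ref = "normal"
    elif reference_dist == "t":
        if df is None or df < 1:
            raise ValueError("t reference requires df >= 1")
        p = 2.0 * stats.t.sf(abs(z), df)
        q = stats.t.ppf(1 - (1 - level) / 2, df)
        ref = f"t({df})"
    else:
        raise ValueError(f"unknown reference distribution {reference_dist!r}")
    return WaldResult(
        estimate=float(estimate),
        se=float(se),
        statistic=float(z),
        p_value=float(p),
        ci_lower=float(estimate - q * se),
        ci_upper=float(estimate + q * se),
        level=level,
        reference_dist=ref,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Standard FDR adjustment across a family of tests: order-preserving,
    never below the raw p-value, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
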