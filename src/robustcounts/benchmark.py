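"""Monte-Carlo orchestration of the variance-estimator comparison.

A *cell* is one (generating family, effect size, covariance method) triple:
``n_reps`` datasets of size ``n`` are drawn with a balanced binary covariate
and log-linear mean, each is fit by Poisson IRLS, the chosen covariance
estimators are applied, and the per-replicate Wald decisions are condensed
into Bias / SEE / SEM / MSE / CP and the rejection rate.  ``run_benchmark``
sweeps settings x families and serialises one summary table per combination.

Seeding: the master seed spawns a per-cell seed, which spawns per-replicate
seeds through ``numpy.random.SeedSequence`` tuples, so any single replicate
(and its bootstrap stream) is reproducible in isolation and independent of
execution order.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .covariance import (
    METHODS,
    bootstrap_cov,
    hc3_sandwich_cov,
    negbin_fit_cov,
    poisson_naive_cov,
    quasipoisson_cov,
)
from .glm import DesignResponse, irls_fit
from .inference import wald_test
from .metrics import ReplicateBatch, summarize_replicates
from .simulate import FAMILIES, gen_covariate, sample_family

__all__ = ["BenchmarkSpec", "run_cell", "run_benchmark", "DEFAULT_SETTINGS"]

logger = logging.getLogger(__name__)

# effect sizes of the three study settings: null, small, large
DEFAULT_SETTINGS = ((2.0, 0.0), (2.0, 0.1), (2.0, 1.5))

_MAX_FAILURE_FRACTION = 0.05


@dataclass
class BenchmarkSpec:
    """Full sweep specification: settings x families x methods."""

    settings: tuple = DEFAULT_SETTINGS
    families: tuple = FAMILIES
    methods: tuple = ("negbin", "poisson_naive", "bootstrap", "sandwich_hc3", "quasipoisson")
    n: int = 200
    n_reps: int = 500
    bootstrap_B: int = 1000
    alpha: float = 0.05
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not self.settings or not self.families or not self.methods:
            raise ValueError("settings, families and methods must be non-empty")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
        for f in self.families:
            if f not in FAMILIES:
                raise ValueError(f"unknown family {f!r}")


def _cov_for(method, fit, X, data, B, boot_seed):
    """Per-method (estimates, covariance, reference) for one replicate."""
    if method == "poisson_naive":
        return fit.beta, poisson_naive_cov(fit, X), ("normal", None)
    if method == "sandwich_hc3":
        return fit.beta, hc3_sandwich_cov(fit, X), ("normal", None)
    if method == "quasipoisson":
        res = quasipoisson_cov(fit, X)
        return fit.beta, res, ("t", res.meta["df"])
    if method == "bootstrap":
        return fit.beta, bootstrap_cov(data, B=B, seed=boot_seed), ("normal", None)
    if method == "negbin":
        nb_fit, res = negbin_fit_cov(data)
        return nb_fit.beta, res, ("normal", None)
    raise ValueError(f"unknown method {method!r}")


def run_cell(
    family: str,
    beta0: float,
    beta1: float,
    method,
    n: int = 200,
    n_reps: int = 500,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Run one simulation cell for one or several covariance methods.

    Methods passed together share the simulated datasets and the Poisson
    fit, mirroring the study design in which every estimator sees the same
    replicates (hence identical Bias/SEE/MSE across methods).

    Returns
    -------
    dict mapping method name to a record with keys ``params`` (list of
    per-parameter metric dicts, order [beta0, beta1]), ``n_failed``,
    ``n_used`` and ``valid`` (False when more than 5% of replicates failed).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 (SEE undefined otherwise)")
    methods = [method] if isinstance(method, str) else list(method)
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")

    x = gen_covariate(n)
    X = np.column_stack([np.ones(n), x])
    truth = np.array([beta0, beta1])
    level = 1 - alpha
    rows: dict[str, list] = {m: [] for m in methods}
    n_failed = {m: 0 for m in methods}

    for rep in range(n_reps):
        ss = np.random.SeedSequence((seed, rep))
        data_seed, boot_seed = ss.spawn(2)
        rng = np.random.default_rng(data_seed)
        mu = np.exp(beta0 + beta1 * x)
        y = sample_family(family, mu, rng)
        try:
            data = DesignResponse(y, X)
            fit = irls_fit(data)
            if not fit.converged:
                raise RuntimeError("IRLS non-convergence")
        except Exception as exc:  # replicate-level failure
            logger.warning("replicate %d fit failed: %s", rep, exc)
            for m in methods:
                n_failed[m] += 1
            continue
        for m in methods:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    beta, res, (ref, df) = _cov_for(m, fit, X, data, B, boot_seed)
                tests = [
                    wald_test(b, s, level=level, reference_dist=ref, df=df)
                    for b, s in zip(beta, res.se)
                ]
            except Exception as exc:
                logger.warning("replicate %d method %s failed: %s", rep, m, exc)
                n_failed[m] += 1
                continue
            rows[m].append(
                (
                    beta.copy(),
                    res.se.copy(),
                    np.array([t.ci_lower for t in tests]),
                    np.array([t.ci_upper for t in tests]),
                    np.array([t.p_value < alpha for t in tests]),
                )
            )

    out = {}
    for m in methods:
        used = rows[m]
        if len(used) < 2:
            raise RuntimeError(f"cell {family}/{m}: fewer than 2 usable replicates")
        batch = ReplicateBatch(
            estimates=np.array([r[0] for r in used]),
            ses=np.array([r[1] for r in used]),
            ci_lower=np.array([r[2] for r in used]),
            ci_upper=np.array([r[3] for r in used]),
            rejected=np.array([r[4] for r in used]),
            truth=truth,
        )
        out[m] = {
            "params": summarize_replicates(batch),
            "n_failed": n_failed[m],
            "n_used": len(used),
            "valid": n_failed[m] <= _MAX_FAILURE_FRACTION * n_reps,
        }
        if not out[m]["valid"]:
            logger.warning(
                "cell %s/%s flagged invalid: %d/%d replicates failed",
                family, m, n_failed[m], n_reps,
            )
    return out


def cell_table(cell: dict, beta1: float, methods=None) -> pd.DataFrame:
    """Arrange one cell's metrics as a parameter x metric table, methods as
    columns — the layout of the study's summary tables."""
    methods = list(cell) if methods is None else list(methods)
    rate_label = "Type I error" if beta1 == 0 else "power"
    index = []
    for pname in ("beta0", "beta1"):
        for metric in ("Bias", "SEE", "SEM", "MSE", "CP"):
            index.append((pname, metric))
        if pname == "beta1":
            index.append((pname, rate_label))
    data = {}
    for m in methods:
        params = cell[m]["params"]
        col = []
        for j, pname in enumerate(("beta0", "beta1")):
            rec = params[j]
            col.extend([rec["bias"], rec["see"], rec["sem"], rec["mse"], rec["cp"]])
            if pname == "beta1":
                col.append(rec["rejection_rate"])
        data[m] = col
    return pd.DataFrame(
        data, index=pd.MultiIndex.from_tuples(index, names=["parameter", "metric"])
    )


def _cell_seed(master_seed: int, si: int, fi: int) -> int:
    ss = np.random.SeedSequence((master_seed, si, fi))
    return int(ss.generate_state(1)[0] % (2**31))


def run_benchmark(spec: BenchmarkSpec, out_dir=None) -> dict:
    """Sweep settings x families; return (and optionally write) one table per
    combination plus a JSON-able run report.

    Deterministic given ``spec.master_seed``.  Tables are TSVs with a
    provenance header (seed, reps, B, package version).
    """
    tables = {}
    report = {
        "seed": spec.master_seed,
        "n": spec.n,
        "n_reps": spec.n_reps,
        "bootstrap_B": spec.bootstrap_B,
        "version": __version__,
        "cells": [],
    }
    for si, (b0, b1) in enumerate(spec.settings):
        for fi, family in enumerate(spec.families):
            seed = _cell_seed(spec.master_seed, si, fi)
            logger.info("cell setting=%d family=%s seed=%d", si, family, seed)
            cell = run_cell(
                family, b0, b1, list(spec.methods),
                n=spec.n, n_reps=spec.n_reps, B=spec.bootstrap_B,
                alpha=spec.alpha, seed=seed,
            )
            table = cell_table(cell, b1, spec.methods)
            tables[(si, family)] = table
            report["cells"].append(
                {
                    "setting": si,
                    "beta0": b0,
                    "beta1": b1,
                    "family": family,
                    "seed": seed,
                    "n_failed": {m: cell[m]["n_failed"] for m in spec.methods},
                    "valid": all(cell[m]["valid"] for m in spec.methods),
                }
            )
            if out_dir is not None:
                out_dir = Path(out_dir)
                out_dir.mkdir(parents=True, exist_ok=True)
                path = out_dir / f"setting{si + 1}_{family}.tsv"
                with open(path, "w") as fh:
                    fh.write(
                        f"# robustcounts {__version__} benchmark | "
                        f"seed={spec.master_seed} n={spec.n} reps={spec.n_reps} "
                        f"B={spec.bootstrap_B} beta0={b0} beta1={b1} family={family}\n"
                    )
                    table.to_csv(fh, sep="\t")
    if out_dir is not None:
        with open(Path(out_dir) / "run_report.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return {"tables": tables, "report": report}
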