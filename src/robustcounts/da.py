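"""Per-taxon differential abundance testing with robust standard errors.

Workflow: filter taxa by prevalence, then fit each retained taxon's counts
with a Poisson log-linear model — exposure plus adjustment covariates, and
log library size as a fixed offset (total-sum scaling, so coefficients act
on relative abundance) — compute the chosen robust covariance, Wald-test the
exposure coefficient, and Benjamini-Hochberg-adjust across taxa.

Library sizes are the column totals of the *unfiltered* count matrix, so
offsets are faithful to the sequencing depth even after taxa are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

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
from .inference import bh_adjust, wald_test

__all__ = ["AbundanceStudy", "prevalence_filter", "fit_all_taxa", "run_da"]


@dataclass
class AbundanceStudy:
    """Count matrix (taxa x samples) plus per-sample covariates.

    ``library_sizes`` are computed from the count matrix at construction and
    preserved through filtering.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    library_sizes: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.metadata.index):
            missing = set(self.counts.columns) ^ set(self.metadata.index)
            if missing:
                raise ValueError(
                    f"sample identifiers disagree between counts and metadata: {sorted(missing)[:5]}"
                )
            # same set, different order: align metadata to counts
            self.metadata = self.metadata.loc[self.counts.columns]
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            self.library_sizes = self.library_sizes.loc[self.counts.columns]

    @classmethod
    def from_files(cls, counts_path, metadata_path) -> "AbundanceStudy":
        """Read counts (first column taxon ID) and metadata (first column
        sample ID) from TSV/CSV; the delimiter is sniffed from the suffix."""
        def _read(path):
            sep = "," if str(path).endswith(".csv") else "\t"
            return pd.read_csv(path, sep=sep, index_col=0, comment="#")

        return cls(counts=_read(counts_path), metadata=_read(metadata_path))


def prevalence_filter(
    counts: pd.DataFrame, threshold: float
) -> tuple[pd.DataFrame, dict]:
    """Keep taxa observed (count > 0) in at least ``threshold`` of samples.

    Returns the filtered matrix and a report with per-taxon prevalences and
    the identities of dropped taxa.
    """
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    prevalence = (counts > 0).mean(axis=1)
    keep = prevalence >= threshold
    report = {
        "threshold": threshold,
        "n_input": counts.shape[0],
        "n_kept": int(keep.sum()),
        "dropped": counts.index[~keep].tolist(),
        "prevalence": prevalence,
    }
    return counts.loc[keep], report


def _build_design(
    metadata: pd.DataFrame, exposure: str, adjust_covariates
) -> tuple[np.ndarray, list[str]]:
    """Intercept + exposure + adjusters design; categoricals dummy-coded
    (first level dropped).  The exposure must be numeric or two-level."""
    if exposure not in metadata.columns:
        raise ValueError(f"exposure {exposure!r} not in metadata")
    cols = [exposure] + list(adjust_covariates)
    for c in cols:
        if c not in metadata.columns:
            raise ValueError(f"covariate {c!r} not in metadata")
    sub = metadata[cols].copy()
    exp_col = sub[exposure]
    if not pd.api.types.is_numeric_dtype(exp_col):
        levels = sorted(exp_col.astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"categorical exposure must have exactly 2 levels, got {levels}"
            )
        sub[exposure] = (exp_col.astype(str) == levels[1]).astype(float)
    if sub[exposure].nunique() < 2:
        raise ValueError("exposure is constant across samples")
    design = pd.get_dummies(sub, drop_first=True, dtype=float)
    # keep the exposure as the first column after the intercept
    ordered = [exposure] + [c for c in design.columns if c != exposure]
    design = design[ordered]
    X = np.column_stack([np.ones(len(design)), design.values])
    return X, ["intercept"] + list(design.columns)


def fit_all_taxa(
    study: AbundanceStudy,
    exposure: str,
    adjust_covariates=(),
    method: str = "sandwich_hc3",
    B: int = 1000,
    seed: int | None = None,
    alpha_level: float = 0.95,
) -> pd.DataFrame:
    """Per-taxon Poisson fits with TSS offset and the chosen covariance.

    Returns a table with one row per taxon in ``study.counts``: estimate
    (log-fold change per exposure unit), se, statistic, p, BH-adjusted p,
    method, convergence flag and prevalence.  Taxa whose fit fails (all-zero
    counts, non-convergence, separation) get NA statistics and are excluded
    from the BH family.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    X, names = _build_design(study.metadata, exposure, adjust_covariates)
    offset = np.log(study.library_sizes.values.astype(float))
    if not np.all(np.isfinite(offset)):
        raise ValueError("zero library size: cannot form log offset")
    j = 1  # exposure coefficient index (after intercept)
    prevalence = (study.counts > 0).mean(axis=1)

    records = []
    for t, taxon in enumerate(study.counts.index):
        y = study.counts.loc[taxon].values.astype(float)
        rec = {
            "taxon": taxon,
            "estimate": np.nan,
            "se": np.nan,
            "statistic": np.nan,
            "p": np.nan,
            "method": method,
            "converged": False,
            "prevalence": float(prevalence.loc[taxon]),
            "note": "",
        }
        try:
            data = DesignResponse(y, X, offset=offset)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if method == "negbin":
                    fit, res = negbin_fit_cov(data)
                else:
                    fit = irls_fit(data)
                    if method == "poisson_naive":
                        res = poisson_naive_cov(fit, X)
                    elif method == "sandwich_hc3":
                        res = hc3_sandwich_cov(fit, X)
                    elif method == "quasipoisson":
                        res = quasipoisson_cov(fit, X)
                    else:
                        taxon_seed = np.random.SeedSequence((seed, t)) if seed is not None else None
                        res = bootstrap_cov(data, B=B, seed=taxon_seed)
            if not fit.converged:
                rec["note"] = "non-convergence"
                records.append(rec)
                continue
            ref, df = ("t", res.meta["df"]) if method == "quasipoisson" else ("normal", None)
            w = wald_test(fit.beta[j], res.se[j], level=alpha_level, reference_dist=ref, df=df)
            rec.update(
                estimate=w.estimate, se=w.se, statistic=w.statistic,
                p=w.p_value, converged=True,
            )
        except Exception as exc:
            rec["note"] = str(exc)
        records.append(rec)

    table = pd.DataFrame.from_records(records).set_index("taxon")
    ok = table["p"].notna()
    table["p_bh"] = np.nan
    if ok.any():
        table.loc[ok, "p_bh"] = bh_adjust(table.loc[ok, "p"].values)
    cols = ["estimate", "se", "statistic", "p", "p_bh", "method", "converged", "prevalence", "note"]
    return table[cols]


def run_da(
    study: AbundanceStudy,
    exposure: str,
    adjust_covariates=(),
    method: str = "sandwich_hc3",
    prevalence: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Prevalence-filter then test every retained taxon.

    Offsets use the library sizes of the unfiltered matrix (total-sum
    scaling over all taxa).
    """
    filtered, report = prevalence_filter(study.counts, prevalence)
    sub = AbundanceStudy(
        counts=filtered, metadata=study.metadata, library_sizes=study.library_sizes
    )
    results = fit_all_taxa(
        sub, exposure, adjust_covariates=adjust_covariates,
        method=method, B=B, seed=seed,
    )
    return results, report


def write_results(path, results: pd.DataFrame, provenance: str = "") -> None:
    """Write a result table as TSV with a provenance comment header."""
    with open(path, "w") as fh:
        fh.write(f"# robustcounts {__version__} dafit {provenance}\n")
        results.to_csv(fh, sep="\t")
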