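"""Synthetic data generators for the variance-estimation study.

Single-taxon mode draws a response with log-linear mean
``mu_i = exp(beta0 + beta1 x_i)`` on an exactly balanced binary covariate,
under five mean-variance laws chosen to bracket the behaviour of real
abundance counts:

==============  ===========================  ====================
family          distribution                 variance
==============  ===========================  ====================
gamma_misspec   Gamma(k=mu^1.5, th=mu^-0.5)  mu^0.5  (under-disp.)
poisson         Poisson(mu)                  mu
pareto          Pareto I (shape 5, 0.8*mu)   mu^2/15 (heavy tail)
od_poisson      NB(size=mu)                  2*mu
negbin          NB(size=0.1)                 10*mu^2 + mu
==============  ===========================  ====================

Gamma and Pareto responses are continuous and left unrounded — the stated
variance laws hold only for the un-rounded draws, and the Poisson
quasi-score accepts any real y >= 0.

Multi-taxon mode emits a taxa-by-samples count matrix with a known set of
covariate-associated taxa, for exercising the per-taxon pipeline end to end
without any external reference dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES",
    "SimConfig",
    "gen_covariate",
    "gen_response",
    "sample_family",
    "gen_multitaxon",
    "write_dataset",
]

FAMILIES = ("gamma_misspec", "poisson", "pareto", "od_poisson", "negbin")

_PARETO_SHAPE = 5.0
_NB_SIZE = 0.1


@dataclass
class SimConfig:
    """One simulation cell: n=200 samples, 500 replicates by default."""

    n: int = 200
    beta0: float = 2.0
    beta1: float = 0.0
    family: str = "poisson"
    n_reps: int = 500
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n % 2 != 0:
            raise ValueError("n must be even for an exact 50/50 split")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def gen_covariate(n: int) -> np.ndarray:
    """Fixed balanced binary design: first n/2 zeros, then n/2 ones.

    A fixed design (rather than Bernoulli draws) gives the exact 50/50 split
    of the study design and rules out degenerate replicates.
    """
    if n % 2 != 0:
        raise ValueError("n must be even for an exact 50/50 split")
    return np.repeat([0.0, 1.0], n // 2)


def sample_family(family: str, mu: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one observation per element of ``mu`` from the named family."""
    mu = np.asarray(mu, dtype=float)
    if family == "gamma_misspec":
        return rng.gamma(shape=mu**1.5, scale=mu**-0.5)
    if family == "poisson":
        return rng.poisson(mu).astype(float)
    if family == "pareto":
        # inverse CDF: x_m * U^(-1/shape), with x_m = (1 - 1/shape) * mu
        xm = (1.0 - 1.0 / _PARETO_SHAPE) * mu
        u = rng.uniform(size=mu.shape)
        return xm * u ** (-1.0 / _PARETO_SHAPE)
    if family == "od_poisson":
        # NB with per-observation size mu: Var = mu + mu^2/mu = 2*mu
        return rng.negative_binomial(mu, 0.5).astype(float)
    if family == "negbin":
        p = _NB_SIZE / (_NB_SIZE + mu)
        return rng.negative_binomial(_NB_SIZE, p).astype(float)
    raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")


def gen_response(
    x: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Response draws with mean ``exp(beta0 + beta1 * x)`` under config.family."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mu = np.exp(config.beta0 + config.beta1 * np.asarray(x, dtype=float))
    return sample_family(config.family, mu, rng)


def gen_multitaxon(
    n_samples: int = 400,
    n_taxa: int = 100,
    signal_fraction: float = 0.1,
    effect: float = 0.2,
    seed: int | None = None,
    baseline_logmean: float = 3.0,
    baseline_logsd: float = 1.5,
    size: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Parametric multi-taxon count generator with known truth labels.

    Exactly ``round(signal_fraction * n_taxa)`` taxa (a seeded random subset)
    carry a log-mean slope ``effect`` on a uniform(0, 1) covariate; the rest
    have slope zero.  Baseline abundances vary log-normally across taxa and
    counts are negative binomial with size ``size`` (``size=np.inf`` gives
    Poisson counts), emulating the spread and overdispersion of amplicon
    data without template resampling from any real study.

    Returns
    -------
    counts : DataFrame (taxa x samples) of non-negative integers.
    covariate : Series indexed by sample.
    truth : boolean array, True for covariate-associated taxa.
    """
    if not 0 <= signal_fraction <= 1:
        raise ValueError("signal_fraction must be in [0, 1]")
    if n_samples < 1 or n_taxa < 1:
        raise ValueError("n_samples and n_taxa must be positive")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=n_samples)
    n_signal = int(round(signal_fraction * n_taxa))
    truth = np.zeros(n_taxa, dtype=bool)
    truth[rng.choice(n_taxa, size=n_signal, replace=False)] = True
    base = rng.lognormal(mean=baseline_logmean, sigma=baseline_logsd, size=n_taxa)
    slope = np.where(truth, effect, 0.0)
    mu = base[:, None] * np.exp(slope[:, None] * x[None, :])
    if np.isinf(size):
        counts = rng.poisson(mu)
    else:
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    taxa = [f"taxon_{j:04d}" for j in range(n_taxa)]
    samples = [f"sample_{i:04d}" for i in range(n_samples)]
    counts_df = pd.DataFrame(counts, index=taxa, columns=samples)
    covariate = pd.Series(x, index=samples, name="exposure")
    return counts_df, covariate, truth


def write_dataset(path, y: np.ndarray, x: np.ndarray) -> None:
    """Write a single-taxon simulated dataset as a samples x [y, x] TSV."""
    pd.DataFrame({"y": y, "x": x}).to_csv(path, sep="\t", index=False)
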