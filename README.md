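# robustcounts

Robust variance estimation for count regression, built for microbiome
differential abundance analysis.

Microbiome abundance counts are right-skewed and heteroscedastic: the
variance of a taxon's counts rarely tracks its mean the way the Poisson law
(Var = μ) assumes, and parametric fixes (negative binomial, generalized
Poisson, quasi-Poisson) each impose their own variance law that real data
routinely violate.  `robustcounts` takes a different route: estimate the
coefficients of the log-linear mean model

```
log μ_i = o_i + x_i' β,        E[y_i] = μ_i
```

by Poisson iteratively-reweighted least squares — consistent for β whenever
the *mean* model is right, whatever the variance — and then estimate
Cov(β̂) robustly, by either

- the **HC3 sandwich**:
  `(X'WX)⁻¹ X' diag((e_i/(1−h_ii))²) X (X'WX)⁻¹` with response residuals
  `e = y − μ̂`, IRLS weights `W = diag(μ̂)` and hat-matrix leverages
  `h_ii`, or
- the **case-resampling bootstrap**: the empirical covariance of β̂ over B
  joint resamples of the rows of `(y, X, offset)`.

Both are consistent under arbitrary mean-variance misspecification; naive
Poisson, quasi-Poisson and negative binomial covariances are included as
baselines.  A per-taxon pipeline applies the method to taxa × samples count
tables with a log-library-size offset (total-sum scaling), prevalence
filtering, covariate adjustment and Benjamini–Hochberg correction, and a
benchmark module reproduces the full calibration study (type I error,
power, coverage, SEM vs SEE) under five generating distributions.

## Worked example

Overdispersed counts (Var = 2μ) on a balanced binary exposure, true effect
β₁ = 0.3:

```python
import numpy as np
from robustcounts import PoissonRegression
from robustcounts.simulate import gen_covariate, sample_family

rng = np.random.default_rng(0)
x = gen_covariate(200)                                  # 100 zeros, 100 ones
y = sample_family("od_poisson", np.exp(2.0 + 0.3 * x), rng)

for ct in ("naive", "hc3"):
    print(ct)
    print(PoissonRegression(cov_type=ct).fit(x.reshape(-1, 1), y).summary().round(4))
```

```
naive
           estimate      se  statistic  p_value  ci_lower  ci_upper
intercept    2.0757  0.0354    58.5990      0.0    2.0063    2.1451
x0           0.2239  0.0475     4.7121      0.0    0.1308    0.3170

hc3
           estimate      se  statistic  p_value  ci_lower  ci_upper
intercept    2.0757  0.0533    38.9405   0.0000    1.9712    2.1802
x0           0.2239  0.0768     2.9136   0.0036    0.0733    0.3745
```

The point estimates are identical — variance estimation never touches the
fit — but the model-based SEs are ~40% too small under Var = 2μ (0.0475 vs
the honest 0.0768 for the slope), which is exactly the mechanism that
inflates false discoveries in per-taxon testing.  Estimators are
scikit-learn compatible (`get_params`/`set_params`, `fit`/`predict`,
pipelines); the functional API (`irls_fit`, `hc3_sandwich_cov`,
`bootstrap_cov`, ...) exposes the same computations on raw design matrices.

## Differential abundance on a count table

```sh
robustcounts dafit --counts counts.tsv --metadata meta.tsv \
    --exposure case_status --adjust sex,batch \
    --method sandwich_hc3 --prevalence 0.05 --out results.tsv
```

`counts.tsv` is taxa × samples (first column taxon IDs), `meta.tsv` is
samples × covariates (first column sample IDs).  Each retained taxon is fit
with log library size (computed before filtering) as offset; the output
table has the exposure log-fold-change, robust SE, Wald p and BH-adjusted p
per taxon.  `robustcounts benchmark` runs the simulation study
(`--families`, `--settings`, `--methods`, `--reps`, `--bootstrap-b`,
`--seed`, `--out`).

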