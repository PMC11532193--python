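# Methods

## Model and estimation

For one taxon with counts `y_1..y_n`, covariate rows `x_i` (including the
intercept) and optional log-scale offsets `o_i`, the mean model is
log-linear: `E[y_i] = μ_i = exp(o_i + x_i'β)`.  β is estimated by Poisson
maximum likelihood via Fisher scoring (IRLS),

```
β_{k+1} = β_k + (X' W_k X)⁻¹ X' (y − μ_k),    W_k = diag(μ_k),
```

initialised from an intercept-only model (intercept = log of the mean
response, adjusted by the mean offset when offsets are present; all other
coefficients zero) and stopped when `‖β_{k+1} − β_k‖₂ < tol`
(default `1e-8`, `max_iter = 50`).  At convergence the score
`X'(y − μ̂)` vanishes, so β̂ solves the Poisson quasi-score equations.
The key robustness property: these equations identify β under *any* true
variance law, and for any real `y ≥ 0` — continuous responses (the Gamma
and Pareto simulation arms) are accepted unrounded.  Responses that are
identically zero are rejected (the initialisation is undefined and the fit
carries no information); the abundance pipeline filters such taxa upstream.

Leverages are the diagonal of the GLM hat matrix `H = X(X'WX)⁻¹X'W`, whose
diagonal equals that of the symmetric `W½X(X'WX)⁻¹X'W½` form, so
`h_ii ∈ (0,1)` and `trace(H) = p`.

## Covariance estimators

All estimators below are evaluated at the same β̂; they differ only in how
they turn residual variation into Cov(β̂).

- **Naive Poisson** — inverse information `(X'WX)⁻¹`.  Correct only under
  Var = μ; badly anti-conservative under overdispersion, conservative
  under underdispersion.
- **HC3 sandwich** — `(X'WX)⁻¹ X' diag((e_i/(1−h_ii))²) X (X'WX)⁻¹` with
  `e = y − μ̂`.  The 1/(1−h_ii) inflation corrects the small-sample
  downward bias of the plain (HC0) sandwich; HC3 SEs dominate HC0 SEs
  elementwise.  A leverage of exactly 1 is reported as an error with the
  offending sample index.
- **Bootstrap** — B case resamples (rows of `(y, X, offset)` jointly, with
  replacement), each refit by IRLS, empirical covariance with denominator
  B−1.  Default B = 1000.  Resamples whose design collapses (a covariate
  level vanishing, or an all-zero response) are redrawn and counted; if
  degenerate draws exceed 10% of B the bootstrap aborts — at that point
  the data, not the resampler, are the problem.  The B refits run as one
  vectorised batched Fisher-scoring sweep, which keeps a full
  500-replicate × B=1000 benchmark cell under a minute.
- **Quasi-Poisson** — `φ̂ (X'WX)⁻¹` with the Pearson dispersion
  `φ̂ = Σ e_i²/μ_i / (n−p)`.  Exact under Var = φμ; with a strongly
  nonlinear variance law (e.g. Var ≈ 10μ²) and a wide μ range it
  *over*-states SEs and loses power.
- **Negative binomial (NB2)** — full ML fit with Var = μ + μ²/r,
  alternating Fisher scoring for β with a bounded 1-D profile-likelihood
  search over log r; covariance is the inverse expected information for β
  at (β̂, r̂).  If r̂ reaches the equidispersion ceiling (1e7) the Poisson
  covariance is returned with a warning.  Non-integer responses are
  accepted as a quasi-likelihood (Γ-function form at real y) with a
  warning.  On saturated designs (e.g. the balanced two-group study
  design) the NB score equations reduce to group means, so the NB β̂
  coincides with the Poisson β̂ — which is why simulation Bias/SEE/MSE
  rows are identical across methods.

## Inference

Two-sided Wald tests `β̂/SE` with symmetric intervals `β̂ ± q·SE`.  The
reference distribution is standard normal for the naive, sandwich,
bootstrap and NB covariances and t with n−p degrees of freedom for
quasi-Poisson, matching the conventions of the standard GLM software
stacks (a choice, since Wald references are convention, not theory).
Bootstrap intervals are Wald-type from the bootstrap SE, not percentile
intervals — the bootstrap here estimates a covariance, nothing more.
Multiplicity is handled by Benjamini–Hochberg step-up adjustment across
taxa (via statsmodels), applied only to taxa whose fit converged.

## Simulation design

Single-taxon cells draw n = 200 observations on a *fixed* balanced binary
covariate (first half 0, second half 1 — the exact 50/50 split of the
study design, with no degenerate replicates) with mean
`μ = exp(β0 + β1 x)`, `β0 = 2` and `β1 ∈ {0, 0.1, 1.5}` (null / small /
large effect), 500 replicates per cell.  Five families share that mean but
disagree on the variance:

| family        | draw                                | variance  | regime |
|---------------|-------------------------------------|-----------|--------|
| gamma_misspec | Gamma(k = μ^1.5, θ = μ^−0.5)        | μ^0.5     | under-dispersed |
| poisson       | Poisson(μ)                          | μ         | correct |
| pareto        | Pareto I, shape 5, x_m = 0.8μ (inverse CDF `x_m U^{−1/5}`) | μ²/15 | heavy-tailed |
| od_poisson    | NB with per-observation size = μ    | 2μ        | mildly over-dispersed |
| negbin        | NB with size r = 0.1                | 10μ² + μ  | severely over-dispersed |

Per-replicate metrics are condensed into Bias, SEE (SD of estimates, N−1),
SEM (mean of estimated SEs), MSE (1/N, so MSE = bias² + SEE²(N−1)/N
identically), CP (0.95-interval coverage) and the α = 0.05 rejection rate.
Seeding is hierarchical (`SeedSequence` tuples master → cell → replicate →
bootstrap stream), so any replicate is reproducible in isolation and
results are independent of execution order.

The multi-taxon generator draws log-normal baseline abundances across taxa
(meanlog 3, sdlog 1.5 — a realistic several-orders-of-magnitude abundance
spread), NB(size = 0.5) counts (strong overdispersion plus natural
sparsity at low baselines), a uniform(0,1) covariate, and gives an exact
`round(signal_fraction·n_taxa)` random subset of taxa a log-mean slope
`effect` (defaults 400 samples, 100 taxa, 10% signal, effect 0.2).  It is
a parametric emulation: it does not reproduce template-resampled real-data
features (taxon-taxon correlation, zero inflation beyond NB sparsity,
compositional closure), so pipeline tests demonstrate calibration and
ordering properties, not performance on any particular real cohort.  One
consequence worth knowing: with a large signal fraction at strong effects,
total-sum-scaling offsets genuinely shift null taxa's *relative*
abundances, so every method's FDR against absolute-abundance truth labels
rises — a property of TSS, not of the variance estimators.

## Differential abundance pipeline

Taxa are filtered at a prevalence threshold (fraction of samples with a
nonzero count; default 5%).  Library-size offsets are the column sums of
the *unfiltered* matrix — total-sum scaling faithful to sequencing depth.
Each retained taxon is fit with intercept + exposure + adjusters
(categoricals dummy-coded, first level dropped; a categorical exposure
must be two-level), the chosen covariance applied, the exposure
coefficient Wald-tested, and BH applied across converged taxa.  Fit
failures (all-zero taxa, separation, non-convergence) yield NA rows with a
reason and are excluded from the BH family rather than silently dropped.

## Numerical choices and limitations

- The linear predictor is clipped at ±500 inside Fisher scoring purely as
  an overflow guard; it is never binding at a solution for data on a sane
  scale.
- Rank deficiency is rejected at construction (exact collinearity) and at
  solve time (singular X'WX).
- Batched bootstrap refits that fail the step-norm criterion within
  `max_iter` are retained at the last iterate with a warning; in the
  study's regimes the observed non-convergence rate is zero.
- The NB size search is bounded in [1e−4, 1e7] on the log scale
  (`minimize_scalar`, bounded Brent).
- Zero-inflated and longitudinal/clustered extensions (GEE-style
  sandwiches) are out of scope; so are compositional transforms (CLR) and
  BIOM/HDF5 ingestion.
- Reported study-scale numbers use 500 replicates and B = 1000, the sizes
  at which the package's own acceptance checks are run; rate metrics then
  carry binomial noise of roughly ±0.01 at 0.05 and ±0.02 at 0.5, which
  is the resolution at which they should be read.
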