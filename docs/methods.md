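# Methods

## Model

`stmrf` fits hierarchical Poisson models for areal count panels.  For
area *i* = 1..S and period *t* = 1..T, with O_it observed events among
N_it at risk:

- **Expected counts** use internal standardization pooled over all areas
  and periods: e_it = N_it · (ΣO / ΣN).  This conserves the total
  (Σe = ΣO exactly) and makes the fitted relative risk ω_it = exp(η_it)
  the multiplicative departure of a cell from the pooled rate.  A cell
  with N_it = 0 gets e_it = 0 and is dropped from the likelihood rather
  than imputed.  Per-period standardization is possible by fitting
  periods separately but is not the default: the pooled rate is what
  makes the temporal trend interpretable as an evolving risk ratio.
- **Likelihood**: O_it ~ Poisson(e_it · ω_it), log ω_it = η_it, so log e
  enters as an offset.
- **Linear predictor**: η = β₀1 + Xβ + (1_T⊗I_S)(v + u) + (I_T⊗1_S)(γ + φ)
  + ψ, laid out time-major (T consecutive blocks of S areas).  Covariates
  are standardized to mean 0, sd 1 (population convention, ddof = 0), and
  may vary in both space and time.
- **Priors**: v ~ ICAR with structure D − A (equivalently, conditional
  mean = average of neighbours, conditional variance = δ_v²/n_i);
  γ ~ RW1; u, φ iid normal; ψ a Knorr-Held interaction of type I–IV with
  structure W_time ⊗ W_space in the same time-major Kronecker order.
  Structure matrices are **not** rescaled to unit generalized variance by
  default; `stmrf.scale_structure` provides the scaled variant for
  sensitivity analysis.
- **Disconnected maps**: the ICAR is improper per connected component;
  every intrinsic prior carries one sum-to-zero constraint per null-space
  dimension (C for the ICAR, 1 for the RW1, the standard Knorr-Held set
  for structured interactions — these arise automatically as the null
  basis of the Kronecker structure).  An isolated area forms a singleton
  component whose constraint pins its structured effect to zero; its iid
  term u_i absorbs the variation.
- **Country splits** (optional): per-component intercepts, per-component
  covariate effects (covariate × component-indicator columns), and
  per-component ICAR variances.  The pooled fit is the non-split model.
- **Hyperpriors**: each log precision θ = log τ has a log-gamma prior,
  Gamma(a = 1, b = 5·10⁻⁴) on τ, a weakly-informative default that admits
  both near-zero and large variances.  Fixed effects get a vague Gaussian
  prior with precision 10⁻⁴ so the joint posterior is proper.

## Inference

The posterior is explored with the Laplace-approximation recipe for
latent Gaussian models:

1. **Constraint handling.**  All constraints A x = 0 are absorbed by
   reparameterizing x = Z z with Z an orthonormal basis of null(A) per
   block.  This is algebraically the same conditioning as
   "conditioning by kriging" but exact and unconditionally stable — the
   intrinsic prior restricted to the subspace is positive definite.
2. **Gaussian approximation.**  For fixed θ, Newton–Raphson on
   log p(z | y, θ) (prior precision + Poisson curvature), with
   step-halving on objective decrease; converged when the max update is
   below 10⁻⁶, capped at 50 iterations (error with trace beyond that).
   Initialization at z = 0, θ = 0.
3. **Hyperparameter posterior.**  log p(θ | y) is approximated by the
   Laplace ratio at the conditional mode (likelihood + prior + generalized
   prior determinant + hyperprior − Gaussian normalizer).  Its mode is
   located by Nelder–Mead (spread initial simplex, tolerance 0.05) and
   per-dimension scales come from finite-difference curvature.
4. **Grid.**  Around the mode, either a full tensor grid (default 5
   points per dimension) or, when the model is too large for that
   (more than ~700 points or a latent dimension above 100), a
   centre-plus-axial design at ±1.2 and ±2.4 scales.  Variance posteriors
   on small instances are strongly skewed, so tensor-grid spans are found
   by scanning outward along each axis until the log posterior drops by 6
   nats — the span is asymmetric where the posterior is.  Weights are the
   normalized posterior values.
5. **Marginals.**  Latent marginals are Gaussian mixtures over the
   weighted grid (simplified Gaussian marginals, not a nested Laplace per
   element); credible intervals use the mixture mean ± 1.96 sd.
   Hyperparameter summaries are weighted moments/quantiles of the grid
   values, reported as **variances**.  Accuracy of these simplifications
   is covered by the MCMC cross-check below.

**MCMC oracle.**  `mcmc_oracle` is a Metropolis-within-Gibbs sampler in
the same constrained parameterization: the latent block uses an
independence proposal from the Gaussian approximation at the current θ
(recomputed lazily when θ moves), log precisions use adaptive random-walk
steps tuned to ~40% acceptance during burn-in.  It is asymptotically
exact and is used in the test suite to validate the approximate scheme on
small instances (fixed-effect posterior means agree within 0.05).

**Orthogonalization (optional).**  With `orthogonalize=True`, the
structured spatial field and the interaction are additionally constrained
orthogonal to the covariate span (Xᵀ(map·effect) = 0 — restricted spatial
regression).  This is an explicit, optional device against spatial
confounding; the default (off) simply includes the covariates.

## Model comparison and reporting

- **DIC** = D̄ + p_D with p_D = D̄ − D(η̂), deviance −2×Poisson
  log-likelihood (unsaturated; constants cancel in comparisons), Monte
  Carlo average over 200 posterior draws from the fitted mixture.  A
  difference above 3 on the same panel is flagged as meaningful.
- **WAIC** = −2(lppd − p_WAIC) from the same pointwise draws.
- **Variance partition** uses empirical variances of the posterior-mean
  effect fields mapped to the full S×T grid — not the hyperparameter
  values, because intrinsic-prior variance parameters are conditional,
  not marginal, variances.  The RW1 trend and the iid period effect are
  reported together as the temporal share.
- **RR transforms**: a coefficient β on a standardized covariate is
  reported as 100·(exp(β) − 1) percent change in relative risk per 1 sd,
  rounded to integers in report labels.

## Synthetic data

`generate_graph` builds disjoint rook-contiguity lattices (default four
components of 11+10+9+7 = 37 districts, truncated near-square grids,
which stay connected under row-major truncation).  `generate_panel`
emulates a multi-country survey-aggregated panel:

- covariates: logistic-squashed Gaussian fields with country-level mean
  shifts (sd 0.6), area effects (sd 0.4) and AR(1) temporal correlation
  ρ = 0.7 — deliberately correlated with the spatial structure to create
  the confounding the model must cope with; defaults overridable;
- at-risk totals uniform on 500–8000 per cell; baseline event probability
  0.09 (mortality of ~90 per 1,000, the scale typical of the application
  domain);
- random effects drawn from their constrained priors by spectral
  sampling (a variance of exactly 0 switches a family off); generating
  variances default to a temporal-trend-dominant regime
  (σ²_γ = 0.3, δ²_v = 0.1, σ²_ψ = 0.05, σ²_u = σ²_φ = 0.02);
- default covariate effects follow the protective/adverse sign pattern
  of the domain (negative for sanitation, water, fuel, literacy, facility
  access; positive for rurality and poverty);
- counts are generated in two passes so the generator and the analysis
  share the same expected-count definition: provisional counts at the
  baseline rate fix the pooled rate, then O ~ Poisson(e·exp(η)), clipped
  at N (a negligible truncation at the default rates).

The generator does **not** emulate two-stage cluster sampling, survey
weights, boundary changes or GPS displacement; passing tests demonstrate
correctness of the model and inference machinery under the stated
generative regime, not robustness to those survey artefacts.

## Problem sizes used in the checks

The statistical test batteries run at the scale of the emulated study:
S = 36–37 areas in 4 components, T = 4 periods, k ≤ 3 active covariates;
coverage uses 40 replicates, DIC selection 20 seeds, partition
attribution 10 seeds; the MCMC cross-checks use 5-area toys with 24,000
iterations.  These sizes make the full suite run in minutes while leaving
the Monte Carlo margins comfortably inside the asserted thresholds.

## Known limitations

- Latent algebra is dense; comfortable to a few thousand latent
  dimensions, not for very large maps.
- Credible intervals use mixture-normal quantiles; strongly skewed latent
  marginals (tiny counts) inherit some approximation error.
- Hyperparameter quantiles come from the exploration grid and are coarse
  when the centre-plus-axial design is in use.
- The RW1/iid temporal split is weakly identified at T = 4; their joint
  contribution (the temporal share) is the stable quantity.
- On very small instances (a handful of areas) the Laplace weighting of
  the hyperparameter posterior inherits visible non-Gaussian error: the
  MCMC cross-checks show fixed-effect posterior means typically agreeing
  within 0.01–0.04, occasionally up to ~0.07 for an unlucky data
  realization at S = 5.  The error shrinks quickly with the number of
  areas per component.
- No RW2/seasonal priors, no Leroux/BYM2 reparameterizations, no
  non-Poisson likelihoods.
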