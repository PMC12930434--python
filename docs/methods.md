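# Methods

## Model

`methvar` tests, per co-methylated region, whether a phenotype is associated
with the *mean* of methylation, its *variability*, or both. On the M-value
scale (log2 odds of methylation, approximately Gaussian), the observation
for CpG `j` of sample `i` within a region is modeled as

```
y_ij | b_i   ~  N(mu_ij, sigma2_ij)
mu_ij          = x_i' beta + delta * G_i + b_i
log sigma2_ij  = x_i' gamma + kappa * G_i
b_i            ~ N(0, sigma_b2)
```

The mean and variance linear predictors share the covariate set `x_i`
(intercept first) and the phenotype `G_i`; neither contains CpG-specific
fixed effects, so CpGs within a region act as exchangeable repeated
measurements of their subject, and the subject random intercept `b_i`
carries the within-region, within-subject correlation. This is the standard
hierarchical-GLM (double-GLM-with-random-effects) structure: a Gaussian
response with identity link in the mean and a log-link model for the
dispersion.

Assumptions worth stating: (i) M-values within a region are
conditionally Gaussian given the subject effect; (ii) the within-region
correlation is exchangeable (compound-symmetry-like) and captured by a
single subject intercept whose variance does not depend on the phenotype;
(iii) regions are independent given the inputs, so they are fit
independently (and can be fit in parallel with identical results);
(iv) region definitions are phenotype-independent and come from upstream
clustering — this package neither builds regions nor preprocesses arrays.

## Estimation

Marginal-likelihood estimation would require integrating the random effects
out of a heteroscedastic model; instead the *hierarchical likelihood* — the
joint log-density of the data and the random effects —

```
h = sum_ij [ -log(2 pi sigma2_ij)/2 - e_ij^2 / (2 sigma2_ij) ]
  + sum_i  [ -log(2 pi sigma_b2)/2 - b_i^2 / (2 sigma_b2) ],     e_ij = y_ij - mu_ij
```

is maximized by alternating three closed updates until every parameter
moves by less than `tol * |old| + abs_tol`:

1. **Mean step.** Given weights `w_ij = 1/sigma2_ij` and `sigma_b2`, the
   maximizer of `h` in `(beta, delta, b)` solves the augmented
   (Henderson-type) normal equations. The subject block is diagonal, so the
   solve reduces to a p x p Schur complement; the fixed-effect covariance
   block supplies `se_delta`, and the diagonal of the augmented hat matrix
   supplies per-observation leverages `q_ij` and per-pseudo-observation
   subject leverages `q_i`.
2. **Variance step.** The score of `h` in `eta_ij = log sigma2_ij` is
   `(e_ij^2/sigma2_ij - 1)/2`, so the squared standardized residuals drive
   a gamma-type log-link GLM. With the leverage correction on (default)
   the response is `d_ij = e_ij^2/(1-q_ij)` with prior weight `(1-q_ij)/2`,
   the REML-flavored choice that removes the downward bias of plug-in
   residuals; with it off, `d = e^2` and weight `1/2`, which makes the
   whole alternation an exact coordinate ascent of the joint likelihood
   (this is the configuration checked against brute-force optimizers in the
   tests). Fisher scoring uses the constant information `X_var' W X_var`
   (factorized once per outer iteration) and warm-starts from the previous
   outer iterate; `se_kappa` comes from its inverse.
3. **Dispersion of the random effect.** The adjusted-profile update
   `sigma_b2 = sum(b_i^2) / sum(1 - q_i)`, which coincides with REML in the
   homoscedastic Gaussian case (verified against a linear-mixed-model REML
   fit in the test suite).

Initialization: `(beta, delta)` by OLS on the stacked design; `(gamma,
kappa)` by regressing `log(max(e^2, floor))` on the variance design;
`sigma_b2` by method of moments on subject-mean residuals, floored at 0.

### Numerical choices and degenerate inputs

- Convergence: relative `1e-6` with absolute floor `1e-8`, outer cap 100,
  inner scoring cap 50 at tolerance `1e-10`. Non-convergence keeps the last
  iterate with `converged=False` (or returns NaN under the `na` policy).
- The log-variance predictor is clamped to ±30 to keep weights finite;
  `1-q` is floored at `1e-6`.
- Singular designs mark the region non-estimable (NaN estimates, flagged);
  all-zero residuals mark it degenerate.
- Single-CpG regions pin `sigma_b2 = 0` (one observation per subject makes
  the intercept unidentifiable) and degrade to a double GLM.
- Wald standard errors are plug-in: `sigma_b2` and the variance parameters
  are treated as known in the mean-model covariance, and conversely. No
  sandwich or finite-sample t correction is applied, so raw p-values run
  slightly hot at small N (empirically ~5.5–6% at alpha = 5% with N = 40,
  approaching nominal as N grows) — exactly the behavior the chi-square(1)
  reference predicts.

## Inference

`W = (estimate/se)^2` is referred to chi-square(1) for `delta` (mean test)
and `kappa` (variance test). The joint p-value is the Cauchy combination
`T = [tan((1/2-p_M)pi) + tan((1/2-p_V)pi)]/2`, `p_joint = 1/2 -
arctan(T)/pi`, valid under arbitrary dependence between the two inputs;
inputs are clamped to `[1e-15, 1-1e-15]` and `tan((1/2-p)pi)` switches to
the stable expansion `1/(p pi)` below `1e-10`. The three families (mean,
variance, joint) are BH-adjusted separately across regions. Calls: the
boolean flags `is_dmr`, `is_vmr`, `is_dvmr` are reported independently
(adjusted p < alpha, default 0.05); the single `call` column uses the
exclusive precedence DVMR > DMR > VMR as a reporting convenience.

## Synthetic data

The generator emulates the benchmark design used to calibrate the method:
regions of 3–10 contiguous CpGs, each sample's CpG vector drawn from a
multivariate normal with compound-symmetry correlation,

```
y_i. ~ MVN( mu0 + mean_effect * g_i ,  sigma2_g [ (1-rho) I + rho J ] ),
sigma2_g = base_sd^2 * var_fold^g,
```

with defaults `rho = 0.5`, `base_sd = 1`, `mu0 = 0`, a 30/70 case–control
split at N = 100, 10,000 regions with 10% true signals, `mean_effect = 0.7`
M-value units and `var_fold = 2.5` (effect grids 0.4/0.7/1.0 and
1.5/2.5/3.5 at N in {50, 100, 150} are supported). Signal regions receive
the mean shift (DMR), the variance fold (VMR) or both (DVMR) uniformly
across their CpGs; label-permutation nulls are provided for type-I studies.
Each region draws from its own counter-based RNG stream keyed by
(seed, region index), so a dataset is a pure function of its config.

One deliberate mismatch between generator and model: under compound
symmetry the *shared* component of variance also scales with `var_fold`,
while the model has a single phenotype-independent `sigma_b2`. The fit
resolves this by attributing the excess shared variance to the residual
term, which biases `kappa` upward by roughly `+0.04` at `rho = 0.5`,
`n_r = 5`, `var_fold = 2.5` (fixed-point calculation, confirmed by the
recovery tests). `delta` is unaffected.

What the generator does **not** emulate: beta-scale boundary effects and
mean–variance coupling of real arrays, probe-level technical noise, batch
structure, cell-composition heterogeneity, irregular probe spacing, and
non-exchangeable within-region correlation. Passing calibration here shows
the estimator and the testing pipeline behave as designed under the stated
generative law — not that real-data FDR is guaranteed at nominal levels
when those features are strong.

## Evaluation metrics

Empirical FDR `FP/max(1, TP+FP)` (an empty discovery set scores 0), power
`TP/max(1, TP+FN)`, MCC (0 when a marginal is empty), rank-based AUROC
(score `1 - p` of the scenario-relevant family, ties counting 1/2), and
type-I error as the fraction of raw p-values below alpha under a global
null — raw rather than adjusted, since adjusted-p type-I under a global
null is degenerate. Power/FDR/MCC are computed on adjusted-p calls,
matching how calls are defined.

## Problem sizes used in the shipped checks

The calibration suite runs 1,000 null regions at N = 40 for type-I; 2,000
regions x 20 seeds per scenario at N = 100 for FDR; 300 regions x 10 seeds
per (scenario, N) cell for power ordering; and 200 replicate regions at
N = 2,000 for parameter recovery. These sizes give Monte-Carlo standard
errors a few times smaller than the tolerances they are checked against.

## Known limitations

- One random effect (subject intercept); multi-level designs
  (e.g. tissue-within-subject) are out of scope for this version.
- Gaussian response only; sequencing-count methylation data would need a
  different family.
- Plug-in Wald inference, mildly anticonservative at small N (see above).
- Missing cells are rejected rather than imputed; imputation is upstream.
- Region construction, array preprocessing, normalization and batch
  correction are upstream responsibilities.
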