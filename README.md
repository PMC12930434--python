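# methvar

Region-based detection of **differential** and **variable** DNA methylation.

Most epigenome-wide association studies characterize dysregulation purely
through shifts in mean methylation. Substantial evidence shows that
phenotype-associated changes also appear as shifts in methylation
*variability*, or as joint mean–variance shifts — patterns that mean-only
pipelines cannot see. `methvar` models both at once, at the level of
biologically defined co-methylated regions, for analysts working with
Illumina-style methylation arrays (450K/EPIC M-values) who already have
per-CpG region assignments from an upstream clustering step.

## Model

For CpG *j* of sample *i* within one region, on the M-value
(logit2-of-beta) scale:

```
y_ij | b_i  ~  N(mu_ij, sigma2_ij)
mu_ij          = x_i' beta + delta * G_i + b_i        (mean model)
log sigma2_ij  = x_i' gamma + kappa * G_i             (variance model)
b_i            ~ N(0, sigma_b2)
```

`G` is the phenotype (binary, continuous or discrete), `x_i` the covariates
(intercept first). The subject random intercept `b_i` absorbs the
correlation of CpGs measured on the same individual — CpGs within a region
are treated as repeated measurements. `delta` is the region's mean
(differential-methylation) effect and `kappa` its log-variance
(variable-methylation) effect.

Estimation maximizes the **hierarchical likelihood** — the joint
log-likelihood of the data and the random effects — by alternating:

1. a weighted mixed-model solve for `(beta, delta, b)` with precisions
   `1/sigma2_ij`;
2. a gamma-type log-link GLM for `(gamma, kappa)` whose response is the
   squared, leverage-corrected residual `e^2/(1-q)` with prior weight
   `(1-q)/2` (consistent with `e^2 ~ sigma2 * chi2_1`);
3. a REML-type update `sigma_b2 = sum(b^2) / sum(1-q_i)`.

Per region, Wald statistics `W = (estimate/se)^2 ~ chi2_1` test `delta = 0`
and `kappa = 0`; the two p-values are combined by the Cauchy combination
test `T = [tan((1/2-p_M)pi) + tan((1/2-p_V)pi)]/2`,
`p_joint = 1/2 - arctan(T)/pi`, valid under arbitrary dependence. Each
p-value family is BH-adjusted separately and regions are called **DMR**
(mean), **VMR** (variance) or **DVMR** (joint) at a configurable alpha.

## Worked example

```bash
methvar simulate --scenario DVMR --n-regions 300 --prop-signal 0.1 \
    --n 100 --mean-effect 0.7 --var-fold 2.5 --group-props 0.7,0.3 \
    --seed 7 --out-prefix demo
methvar fit --mvalues demo.mvalues.tsv --regions demo.regions.tsv \
    --design demo.design.tsv --out demo.results.tsv
methvar evaluate --results demo.results.tsv --truth demo.truth.tsv \
    --scenario DVMR
```

which prints (verbatim):

```
wrote demo.{mvalues,regions,design,truth}.tsv (300 regions, N=100)
wrote demo.results.tsv (300 regions, 24 DMR / 32 VMR / 31 DVMR flags at alpha=0.05)
scenario	alpha	n_regions	fdr	power	mcc	auroc
DVMR	0.05	300	0.0322581	1	0.981915	0.999877
```

Reading the last line: of the 31 regions flagged as jointly dysregulated
(BH-adjusted joint p < 0.05), one is a false discovery (empirical FDR 3.2%,
under the nominal 5%); all 30 planted signal regions are recovered
(power 1.0); MCC 0.98 and AUROC ~1.0 summarize the near-perfect ranking. The
`fit` output table has one row per region with the estimates
(`delta_hat`, `kappa_hat`, `sigma_b2`), their standard errors, the three
p-value families raw and BH-adjusted, and the call.

The same machinery is available as a library. The core fit is a
scikit-learn-style estimator:

```python
from methvar import MeanVarianceHGLM, analyze
m = MeanVarianceHGLM().fit(X, y, groups=subject_ids)
m.delta_, m.se_delta_, m.kappa_, m.se_kappa_, m.sigma_b2_
```

where `X` holds covariates (phenotype as the last column) and `groups`
maps each stacked observation to its subject; `analyze(matrix, regions,
design)` runs the whole per-region pipeline and returns the results table
as a DataFrame.

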