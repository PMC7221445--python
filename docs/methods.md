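# Methods

## The model

`gxescan` tests, gene by gene, whether the eQTLs that regulate a gene's
expression jointly modify the effect of an exposure on case-control disease
risk. For a gene with eQTL dosage matrix `G` (n samples x m variants),
elastic-net-derived weights `w`, predicted expression `x = G w`, exposure `E`
(BMI in units of 5 kg/m^2, or a 0/1 diabetes indicator) and binary outcome
`y`, the working model is logistic:

    logit P(y_i = 1) = a'z_i + b_E E_i + b_x x_i + tau (x_i E_i) + sum_j u_j (G_ij E_i)

with covariates `z` (intercept, age, sex where applicable, study indicators,
principal components). The interaction is split into

* a **fixed (burden-type) component** `tau`, the interaction of predicted
  expression with the exposure, and
* a **random (dispersed) component** `u_j ~ N(0, theta)`, residual SNP-level
  interactions not captured by the expression-weighted combination.

Both components are tested with score tests, so only null models are ever
fitted:

* **Fixed component.** Under the null model *without* any interaction term,
  the score for `s_i = x_i E_i` is `U = sum_i (y_i - mu_i) s_i`. Its efficient
  variance `V` is the squared norm of `sqrt(W) s` after projecting out the
  null design columns under the IRLS weights `W = diag(mu(1-mu))`; `U^2 / V`
  is referred to chi-square(1).
* **Random component.** Under the null model that *includes* the fitted fixed
  interaction term, the variance-component statistic is
  `Q = || C'(y - mu) ||^2` with columns `C_j = E * G_j`. Its null law is
  `sum_k lambda_k chi^2_1` with `lambda_k` the eigenvalues of `C' P C`,
  `P = W - W X (X' W X)^{-1} X' W`. Conditioning the random test on the fixed
  term is what makes the two component p-values asymptotically independent —
  the prerequisite for combining them (verified empirically: correlation of
  the two p-values across null replicates is 0 within Monte-Carlo error).
* **Combination.** Either Fisher's rule (`-2(ln p_fix + ln p_ran)` against
  chi-square(4)) or, by default, an adaptive grid: for weights
  `w in {0, 0.25, 0.5, 0.75, 1}` the statistic
  `-2(w ln p_fix + (1-w) ln p_ran)` has an exact null tail (a weighted sum of
  two independent exponentials); the minimum of the five per-weight p-values
  is referred to its own exact null distribution under independent uniforms,
  computed by numerical integration over the unit square (reduced
  analytically to a one-dimensional integral with breakpoints at the
  constraint intersections, absolute accuracy ~1e-10). The combined p-value
  is therefore exactly uniform under the null given independent components;
  no resampling is involved.

The null model deliberately contains the predicted-expression main effect
`x` but not per-SNP main effects: with up to ~100 eQTLs per gene,
per-SNP main effects would destabilize the fit, and `x` serves as the
gene-level genetic main-effect summary.

## Mixture-of-chi-squares tail

`mixture_chisq_pvalue(q, lambdas)` computes `P(sum_k lambda_k Z_k^2 > q)`:

1. equal eigenvalues: exact scaled chi-square;
2. otherwise a **Ruben series** — the exact expansion of the mixture
   distribution in central chi-square tails with
   `beta = 2 lam_min lam_max / (lam_min + lam_max)`; the coefficients sum to
   one, giving a built-in truncation bound (target 1e-13, capped at 8000
   terms). This is accurate to ~1e-9 through the deep tail and costs well
   under a millisecond for typical spectra;
3. very spread spectra (where Ruben would need too many terms): Imhof
   characteristic-function inversion by adaptive quadrature;
4. last resort: Liu-Tang-Zhang four-moment matching.

Eigenvalues below `1e-8 * lambda_max` are truncated; a spectrum that is
numerically zero relative to the pre-projection column energy yields the
degenerate result p = 1 (e.g. a residual-interaction column already spanned
by the null design). P-values are floored at 1e-300.

## Null model fitting

Logistic null models are fitted by IRLS (coefficient-change tolerance 1e-8,
at most 100 iterations). A coefficient exceeding 30 in absolute value raises
a separation error and the gene is skipped with a log entry. Study
indicators that are collinear with the rest of the design are dropped
silently (a stratum may simply lack one study); any other dependent column —
including a constant exposure — is a hard error, except that a constant
exposure or constant predicted expression is omitted from the design so the
score tests can report their defined degenerate p = 1. The IRLS fit is
cross-checked in the test suite against statsmodels' Newton optimizer
(log-likelihood agreement to 1e-6).

## Scan orchestration

BMI scans run separately in men and women — the BMI-disease association
differs by sex — while diabetes scans pool the sexes and adjust for sex.
Genes enter the scan only if their expression heritability (predictive R^2
of the weight model) is at least 0.01, boundary inclusive. Benjamini-
Hochberg q-values are computed within each exposure-by-stratum scan and
genes flagged at q < 0.2. Three principal components are adjusted by
default (configurable). The exposure main effect (OR per unit E with Wald
95% CI) is estimated by an ordinary pooled logistic fit via statsmodels.

Variant-level QC implements a tiered imputation-quality rule matched from
common to rare: r2 > 0.3 for MAF > 1%, r2 > 0.5 for 0.5% < MAF <= 1%,
r2 > 0.99 for MAF <= 0.5%. The published anchor points leave the exact
boundaries between tiers unstated; half-open tiers were chosen so every
variant matches exactly one tier. Directly typed variants (no imputation
score) always pass. An exact Hardy-Weinberg test on hard-called genotypes
in controls (P < 1e-4) is available but off by default, because HWE on
imputed dosages is ill-defined. The MAF used by the filter is the pooled
cohort MAF.

## Follow-up analyses

For flagged genes, a forward sequential conditional search fits, for every
not-yet-selected eQTL, a logistic model with covariates, exposure, all
previously selected SNP and SNP-by-exposure terms, plus the candidate SNP
and its interaction; the candidate with the smallest interaction Wald
p-value is selected while that p-value stays below 0.05. Ties break toward
the smaller variant index. No backward removal step and no selection-aware
inference correction are applied. Exposure-stratified associations of
predicted expression with the outcome use BMI quartile cut-points computed
in controls only (controls approximate the source population in a
case-control design), or the diabetes indicator.

## Synthetic data

The generator emulates the structure the analysis assumes, not any real
cohort:

* **Genotypes.** Per gene, a latent Gaussian AR-1 process (default rho 0.5)
  thresholded at each variant's MAF (drawn uniformly from 0.05-0.45) gives
  one haplotype; dosage is the sum of two. LD therefore decays
  geometrically along the gene — real human LD blocks are not modelled.
* **Weights.** A sparsity fraction (default 0.3) of variants receive
  standard normal weights, mimicking elastic-net selection. The reported
  predictive R^2 is the empirical variance fraction of the genetic score in
  a noisy expression trait whose noise variance is set so R^2 centres on a
  target (default 0.1, within the 2-15% range typical of colon-tissue
  expression models).
* **Exposures.** Raw BMI ~ Normal(27, 4.5) truncated below at 18.5 kg/m^2,
  stored in /5 units; diabetes is Bernoulli with a logit linear in BMI
  (slope 0.5 per 5 kg/m^2, marginal prevalence ~11%), so the two exposure
  analyses are correlated as in real cohorts.
* **Outcome.** The logistic model above with study-specific intercepts
  (SD 0.2 across 4 studies), age effect 0.02/yr, a small female-protective
  sex effect (-0.2), PC effects 0.05, exposure main effect log(1.25) per
  unit by default, and interaction parameters tau / theta acting on one
  designated causal gene. The baseline log-odds is calibrated by
  root-finding so the population prevalence hits the target (default 10%);
  cases and controls are then sampled retrospectively to the requested
  counts, mirroring the consortium-style design.
* A targeted single-SNP interaction (`snp_interaction_beta`, indexed within
  the causal gene's weight set) supports follow-up selection studies.

All randomness flows from one seeded generator per scenario; the same seed
reproduces a fixture bundle byte for byte.

What passing tests on these data do **not** show: robustness to realistic
LD maps, imputation error processes, cross-study exposure harmonization
artifacts, population stratification beyond simple Gaussian PCs, or
non-European LD/frequency spectra.

## Frozen study conditions for the verification studies

* Null calibration: 1000 cases / 1000 controls, one 30-SNP gene, 500
  replicates; type-I error at alpha 0.05 checked within +/-0.02 for all
  three p-values, KS uniformity of the adaptive p, and component
  independence (|corr| <= 0.05).
* Burden scenario tau = 0.15, dispersed scenario theta = 0.002 (chosen in a
  design-stage power sweep to sit in the clearly-detectable-but-not-
  saturated regime at n = 2000); component attribution requires the correct
  component to win in >= 70% of 200 replicates.
* Score-vs-LRT agreement: 100 replicates at n = 2000, tau = 0.15, ratio of
  -log10 p within [0.7, 1.3] for every replicate.
* Main-effect recovery: OR 1.25 per 5 kg/m^2 recovered within [1.15, 1.35]
  at n = 20000; null-OR CI coverage measured over 800 replicates at
  n = 2000 (within 95% +/- 3%).
* Sequential follow-up: a single-SNP interaction of log-OR 0.3 in a 10-SNP
  gene at n = 4000; the true SNP must be selected first in >= 80% of 100
  replicates.
* The "large burden effect" single-scenario check uses the binary diabetes
  exposure with tau = 0.6: with the BMI exposure, `x*E` is ~0.99-correlated
  with `x` (E is far from zero in /5 units), which caps single-dataset
  power at n = 2000 regardless of tau; the binary exposure keeps the term
  well-identified. This collinearity also explains why BMI-interaction
  power is intrinsically lower than diabetes-interaction power at equal
  effect size.

## Known limitations

* The adaptive combination assumes the two component p-values are exactly
  independent uniforms; this holds only asymptotically, and in small
  samples (n in the low hundreds) the combined p-value can be mildly
  conservative or anticonservative.
* The random-effect test uses raw dosage-by-exposure columns without
  per-variant weighting; rare-variant weighting kernels are out of scope.
* Wald CIs and Wald sequential p-values share the usual logistic
  small-sample behaviour; no Firth correction is attempted (separated fits
  are skipped, not rescued).
* Predicted expression is not re-standardized across genes; both score
  statistics are scale-invariant, so this affects only the interpretation
  of per-unit follow-up ORs.
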