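# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical choices, and the known limitations of `finemapmiss`.

## Model

### Complete-data fine-mapping

For a region of `p` variants with standardized genotypes `X`, a
quantitative phenotype is modeled as `y = Xλ + ε` with a sparse effect
vector `λ`. Non-zero effects carry a `N(0, τ²)` prior, and the causal
configuration `γ ∈ {0,1}^p` carries a truncated binomial prior

    p(γ) ∝ (1/p)^{|γ|} ((p−1)/p)^{p−|γ|} 1(|γ| ≤ kmax),

i.e. one causal variant expected a priori. Only marginal summary
statistics are needed: the z-scores satisfy
`z | γ ~ N(0, R + n τ² R Σ_γ R)` with LD matrix `R`. The Bayes factor of
`γ` against the null reduces to a ratio of |γ|-dimensional Gaussian
densities because the conditional law of the non-causal coordinates given
the causal ones is identical under both models (implemented in
`bf.log_bf_classic`).

### Imputed genotypes

When dosages rather than hard genotypes are the regression predictors,
the LD matrix is defined as the correlation of the predictors and each
variant's effective scale is `I_j = √INFO_j`: the dosage captures only a
fraction `I_j` of the correlation with the underlying genotype. The
marginal–joint effect relationship becomes `λ̂ = I⁻¹ R⁻¹ I β̂`
(`bf.joint_from_marginal`); with `I = 1` everything reverts to the
complete-data model.

### Missingness-aware likelihood

In an inverse-variance-weighted meta-analysis over studies `u = 1..d`
with weights `w_ju = s_ju⁻²` (set to 0 where variant `j` is missing from
study `u`), the covariance between meta z-scores attenuates to
`R_M = R ⊙ M` with

    M[j1,j2] = Σ_u √(w_j1u w_j2u) B_j1j2,u / √(Σ_u w_j1u · Σ_u w_j2u).

`B` deviates from 1 only by terms quadratic in the standardized marginal
effects, which are O(1/n) for polygenic traits; the default therefore
sets `B = 1` (`b_mode="unit"`), and the exact form is available when
per-study effects are known. Both published readings of the printed `B`
formula are implemented (`b_reading="product"|"ratio"`, default the one
consistent with its denominator). The configuration likelihood becomes

    z | γ ~ N(0, R_M + τ² Q_γ Q_γᵀ),   Q_γ = N R[:,C] diag(I_C),

with `N = diag(√n_j)` holding the per-variant *total* sample sizes. The
log Bayes factor is evaluated via the Woodbury identity so only |γ|×|γ|
solves are needed per configuration. Because every column of `Q_γ` is a
column of the fixed matrix `A = N R diag(I)`, the implementation
precomputes the Gram matrix `Aᵀ R_M⁻¹ A` and the vector `Aᵀ R_M⁻¹ z`
once per region; each configuration (and each add/swap batch inside the
search) then costs O(k³) via Schur complements. A dense O(p³)-per-call
evaluation of the same quantity exists purely as a cross-checking oracle.

### Posterior exploration and summaries

Small regions are enumerated exhaustively (configurable cap, default
2×10⁶ configurations). Otherwise a shotgun stochastic search scores the
full add/delete/swap neighborhood of the current configuration each
iteration (default 50 neighborhoods) and samples the next configuration
proportionally to unnormalized posterior mass within the neighborhood.
All scored configurations enter the summaries; normalization uses
log-sum-exp throughout. PIPs, the posterior distribution of the number of
causal variants `K`, and its expectation (PENC = Σ_j PIP_j) are reported.

Credible sets at level θ are built per causal signal of the top
configuration of size `k`: for each anchor `j` in it, every single-variant
replacement of `j` is scored, the resulting conditional probabilities
`b̄` are normalized (the prior cancels, all configurations having equal
size), and variants are collected in decreasing `b̄` until their sum
exceeds θ. `k` defaults to `round(PENC)` clamped to `[1, kmax]` — the
natural plug-in when no external estimate of the signal count exists —
and is exposed as a parameter. Ties at the θ boundary are all included so
coverage never silently falls below θ.

### Summary-statistics imputation (baseline)

Within one study, an unobserved z-score is imputed from the observed set
`O` under the null as `z_{j|O} = R_jO R_OO⁻¹ z_O`; the variance-rescaled
("scaled") version divides by `√(R_jO R_OO⁻¹ R_Oj)`. Completed studies
are then meta-analyzed as if no data were missing — observed entries with
their exact `s⁻²` weights, imputed entries with the
`n_u · 2f(1−f) · INFO` approximation of the weight they would have
carried. The conditioning set is the whole observed region (no
windowing): regions here are at most a few thousand variants, so
windowing would be an optimization, not semantics. This baseline
requires study-level results; public meta-analyses often provide only
combined estimates, which is precisely the setting the missingness-aware
likelihood targets (it only needs the presence pattern, which
`overlap.infer_presence` can reconstruct from per-variant totals and
study sizes when the subset sum is unambiguous).

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `tau2` | 0.05² | prior variance of a standardized causal effect; the long-standing convention of configuration-space fine-mapping software |
| `kmax` | 5 | cap on simultaneous causal variants |
| `iters` | 50 | shotgun-search neighborhoods per run |
| `theta` | 0.95 | credible-set coverage level |
| `b_mode` | `"unit"` | overlap correction term B = 1 |
| ridge ladder | 0, 1e-8, 1e-6, 1e-4 × mean diag | escalating diagonal regularization of `R_M`; first rung whose Cholesky succeeds is recorded in `ridge_used` |
| imputation ridge | 1e-4 × mean diag | regularization of `R_OO`; predictive r² below 1e-4 marks a variant unimputable rather than inflating it |

## Synthetic data

The generator emulates a multi-cohort quantitative-trait GWAS
meta-analysis:

* **Genotypes** are Gaussian-copula draws: correlated latent normals
  thresholded at Hardy–Weinberg cutpoints into {0,1,2}. The latent
  correlation of each within-block pair is calibrated by inverting the
  thresholded-Gaussian covariance integral (Price's theorem, integrated
  with a sin-substitution that removes the r→1 singularity), so the
  *realized genotype* correlation matches the requested block-AR
  structure. Targets unattainable for any latent correlation (e.g. high
  correlation between a rare and a common variant) raise an error; MAFs
  are drawn per block with a small relative jitter because strongly
  correlated variants necessarily have similar frequencies.
* **Imputation noise**: each individual's one-hot genotype probability
  vector is shrunk toward the population (HWE) distribution with weight
  `a = 1 − √INFO`. The dosage (the triple's expectation) then has
  variance `INFO ×` the genotype variance, and "virtual" genotypes
  resampled from the same triples correlate with the dosage by `√INFO` —
  the two properties the analysis model relies on. Phenotypes are driven
  by the virtual genotypes while GWAS sees only dosages.
* **Phenotype**: each causal variant receives `λ = √h2_per_variant`
  (default 0.001, i.e. 0.1% of phenotypic variance) on the standardized
  virtual genotype; residuals are Gaussian with variance `1 − Σλ²`.
* **Missingness**: a fraction (default 20%) of non-causal variants is
  removed from a uniformly chosen nonempty proper subset of cohorts; by
  default each causal variant is present in exactly one cohort — the
  adversarial case for naive fine-mapping. Remaining results are
  IVW-meta-analyzed, and a held-out cohort of the same size provides the
  reference LD (dosage correlation), as in fine-mapping with external LD.

What the generator does **not** emulate: real human LD (heavy-tailed
blocks, long-range structure, near-duplicate imputed variants),
case-control traits, covariates, relatedness, population structure,
between-study LD heterogeneity, and allele-coding errors. Passing tests
therefore demonstrate the statistical mechanics of the likelihood under
its own assumptions, not robustness to every property of real data.

## Scaled-down replicate study

The calibration/power study runs 200 replicates at desk scale: p = 200
variants (block-AR LD, block 20, within-block correlation 0.9, MAF
U(0.05, 0.5) per block), two cohorts of 100,000, INFO U(0.9, 1.0), one
causal variant at 0.1% variance present in one cohort, 20% missingness,
θ = 0.95, default τ² and kmax. The cohort size matches the large-cohort
design this emulates and puts the causal variant's z-score around 9–10;
the region is smaller than a realistic fine-mapping panel so that one
full study completes in about seven minutes on a single CPU.

Two behaviors are checked. First, credible-set power of the
missingness-aware model. Second, PIP-bin calibration: the naive
complete-data model shows the anti-conservative pattern (it assigns
PIP ≈ 1 to non-causal variants at a high rate), while the
missingness-aware model is calibrated in every bin that causal variants
actually reach (in the top bin, 173 of 175 variants at mean PIP 0.991
were causal in one reference run). In the lowest bin (PIP < 0.01) the
missingness-aware model is slightly *conservative* by construction of
the study: the posterior honestly reserves ~0.1 probability for an
additional small causal effect (visible as PENC ≈ 1.1 for a
single-causal truth — the same excess the published PENC values show),
spreading a PIP of order 5×10⁻⁴ over null variants; since the
fixed-effect-size design never generates a causal variant that lands in
that bin, the strict Wilson-interval check there compares an expected
count of ~0.1 per replicate against an observed count of zero and flags
it. This is a property of fixed-`K`, fixed-effect simulations versus a
model averaging over effect sizes, not an error of the method, and its
direction is the safe one.

## Numerical choices

* All Bayes factors are carried in natural log; log10 only at output
  (the exponents overflow doubles at biobank sample sizes).
* The k×k inner solve retries once with a 1e-12 jitter; a configuration
  that still fails scores −∞ rather than aborting the run.
* `R_M` is factorized once (Cholesky) per region with the escalating
  ridge above; the factor backs every solve, including the one-time Gram
  precomputation.
* LD input validation: symmetry to 1e-10 (asymmetry ≤ 1e-8 on file read
  is averaged away), unit diagonal, entries in [−1,1], smallest
  eigenvalue ≥ −1e-8.
* Genotype sampling uses float32 latents (the thresholding destroys any
  precision beyond that); GWAS regression runs in float64.
* Positions are 1-based; allele order is taken as the LD-matrix
  orientation and no strand flipping is attempted. When a per-variant
  `n` column disagrees with the presence table, the presence table wins
  with a warning (it is the quantity the likelihood actually uses).
  Variants observed in zero studies are dropped with a report rather
  than failing the run. A missing INFO column defaults to 1 (genotyped
  assumption).

## Limitations

* The method needs the exact presence structure; inferring it from
  per-variant totals fails when subset sums are ambiguous.
* Reference LD must cover the partially-missing variants and match the
  study population; LD mismatch is not modeled.
* PIPs/PENC are normalized over *evaluated* configurations, the standard
  truncation of stochastic-search fine-mapping.
* The exact-B overlap correction is provided but untested against an
  external reference; its printed formula is ambiguous and both readings
  are exposed.
* Cross-ancestry LD weighting, infinitesimal backgrounds, and
  functional priors are out of scope.
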