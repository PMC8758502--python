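# Methods

`polyscore` implements, end to end, the construction and evaluation of
polygenic scores (PGS) for quantitative, blood-cell-like traits: variant
selection by stepwise conditional analysis, five scoring estimators sharing
one exchange format, a 5-fold internal/external evaluation protocol,
quantile stratification with GAM age trajectories, PGS-by-sex interaction
testing, and a cross-trait PGS-PGS correlation scan. Because the biobank
cohorts such analyses run on are access-controlled, the package ships a
synthetic-cohort generator that reproduces the statistical structure the
analysis depends on; every claim the test suite makes is therefore a claim
about that structure, not about any particular real cohort.

## The generative model

**Genotypes.** Variants are laid out in LD blocks. Within a block, each of a
sample's two haplotypes draws a latent Gaussian
`z = sqrt(r) u + sqrt(1-r) e`, with `u` a per-haplotype block factor shared
by all variants of the block, and the allele is the minor one when `z` falls
below the MAF quantile. Dosage is the sum over the two haplotypes. This
makes across-block variants exactly independent and within-block variants
equicorrelated at latent correlation `r` (default 0.8). The realized
*allelic* correlation is attenuated below `r` by the thresholding —
approximately `(2/pi) arcsin(r)` at MAF 0.5 and more strongly at low MAF —
so at the default `r = 0.8` typical within-block dosage r² is ≈ 0.3–0.4.
Parameters: `n_blocks` (20), `block_size` (100), `maf_range`
((0.005, 0.5)), `low_maf_fraction` (0.2, drawn below MAF 0.05), INFO scores
uniform on [0.4, 1], and an optional uniform missing-call rate. A
coalescent simulator would give more realistic haplotype structure; this
model was chosen because it is fast at desk scale and its LD level is
directly steerable, which the recovery and thinning tests need.

**Trait.** `y = g + w + b_sex·sex + gamma_sex·z(g)·sex + slope_sex·(age-
mean age) + e`, where `g` is the additive genetic value (dosage-scale betas
over the causal set), `w` the sum of centred dosage-product interaction
terms, and `z(g)` the standardized genetic value — the generative twin of a
PGS-by-sex interaction. Products are centred so the interaction terms are
uncorrelated with the main effects, which makes recovery tests sharper.
Additive betas are drawn standard normal and rescaled so `var(g) ≈ 1`
(division by `sqrt(sum beta² · 2f(1-f))`); heritability fixes the
noise-to-signal ratio regardless, the normalization only keeps trait units
interpretable so that sex or interaction coefficients of order 0.1–1 are
visible effects. The noise variance is set from the target SNP
heritability: `var(e) = var(g)(1-h²)/h² - var(w)`, so that
`var(g)/var(y | sex, age fixed) = h²` (default 0.3). Degenerate requests
(h² ≥ 1, interaction variance exceeding the budget) error out. Sex is
Bernoulli(1/2) with male = 1; age uniform on [40, 70] by default (the
external cohort can be given a shifted range); the 10 "principal
components" are standard normals independent of genotype — the analysis
regresses them out, so the default tests that the adjustment is harmless
rather than that it fixes stratification. An optional externally structured
PC mode was deliberately left out of scope.

**External cohort.** Same variant panel and same architecture, fresh
genotype and noise draws — the external-validation role. Any LD difference
between cohorts is a knob (none by default), a modelling choice, not a
claim about real cohort pairs.

## Variant selection

GWAS is simple linear regression of the covariate-adjusted trait (least-
squares residuals on intercept + sex + age + 10 PCs, in the field's usual
pre-adjustment style) on dosage, with t-reference p-values on residual
degrees of freedom — exact at small synthetic n, where the normal reference
is anticonservative.

Conditional analysis (CA) follows the two-stage block-partitioned stepwise
scheme: genome-wide-significant variants (default p < 8.31e-9, the
threshold for common, low-frequency and rare variants) are partitioned per
chromosome into the largest number of blocks such that no two blocks are
closer than 5 Mb and no block exceeds 2,500 variants (oversize blocks are
split into equal contiguous chunks — the cap's split rule is this package's
choice); stepwise selection runs within each block, survivors pool per
chromosome, and stepwise selection runs again. The stepwise routine is
forward (add the candidate with the smallest *conditional* p in the joint
model, subject to conditional p < threshold and pairwise r² < 0.9 with the
current selection; ties break by genomic position) then backward (drop the
worst joint-model p above threshold, iterate to stability). It operates on
individual-level data — the training genotypes are in hand here, so the
joint models are fit exactly rather than approximated from summary
statistics. Whether entry ordering should use marginal or conditional p is
not determined by the protocol's description; conditional p was chosen and
is what the recovery tests certify.

Expanded variant sets: the panel is QC-filtered (strictly MAF > 0.01,
INFO > 0.4, missing rate < 0.1; a looser MAF > 0.005% / INFO > 0.4 profile
exists for the GWAS stage), LD-thinned by a sliding-window greedy
indep-pairwise pass at r² = 0.5 (window 1,000 kb, step 1 variant — window
and step are conventions of this package, exposed in config), and then
tiered by GWAS p at 1e-6, 1e-4, 1e-2 and 1, each tier unioned with the CA
set. Tiers are nested by construction. Thinning removes the member of the
worst pair with the higher missing rate (tie: later position) and is
idempotent. Note that at the generator's default LD (latent r = 0.8,
realized r² ≈ 0.35) the r² = 0.5 thinning pass keeps nearly everything;
panels built with higher `within_block_r` exercise it properly, as the
tests do.

Interaction scans fit `y = b0 + b1 SNP1 + b2 SNP2 + b3 SNP1·SNP2` for all
pairs of a variant set; pairwise LD is squared Pearson correlation of
dosages. All Bonferroni thresholds in the package are computed from the
realized number of tests in the run, never imported from any published
analysis whose test count was different.

## The five estimators

All linear estimators emit a `PGSModel` — ordered (variant, effect allele,
per-dosage weight) — so every score is `PGS_i = sum_j beta_j x_ij`; models
round-trip exactly through PGS-Catalog-style scoring files (17 significant
digits, round-trip float parsing).

* **P+T** copies univariate GWAS betas verbatim onto a pruned/thresholded
  set; no refitting.
* **Elastic net** minimizes
  `sum_i (y_i - PGS_i)² + s·mix·sum|b| + s(1-mix)/2·sum b²` on the
  standardized design. The mixing fraction is fixed at 0.5 and the overall
  strength `s` is tuned on a 10% validation split drawn from the training
  portion only (never the test fold), refitting on the full training data
  at the winning strength. The description of the penalty's two
  coefficients conflicts with the described tuning procedure (both norms
  share a common factor, yet one coefficient is "set to 0.5" and the other
  tuned); fixing the mixing fraction and tuning the overall strength is the
  reading consistent with the tuning procedure and is what is implemented.
  Coordinate descent is scikit-learn's, behind this module's surface, with
  the exact scale mapping `alpha_sklearn = s/(2n)`, `l1_ratio = mix`;
  `strength = 0` falls back to exact least squares. KKT (subgradient)
  optimality of the solution against the objective above is checked
  independently in the tests; the default dual-gap tolerance is 1e-4
  (tighter tolerances are a config knob the optimality tests use). Output
  weights are back-transformed to dosage scale.
* **Bayesian ridge** — Gaussian likelihood precision `alpha`, spherical
  Gaussian weight-prior precision `lambda`, Gamma hyperpriors on both.
  Fitting alternates the closed-form posterior mean (a ridge solve with
  shrinkage `lambda/alpha`, via one thin SVD) with MacKay evidence updates,
  exactly the scheme scikit-learn's BayesianRidge uses — the tests verify
  agreement with it to 1e-8 — but implemented here so precisions can be
  frozen (the closed-form ridge contract) and so the Gamma-hyperparameter
  grid can be scored on the validation split. The published grid contains
  non-positive values, which are improper for Gamma parameters; grid values
  pass through a positivity floor (`max(v, 1e-6)`) and duplicates collapse,
  which is logged in the model provenance. Whether those values were meant
  as raw parameters or exponents is unrecoverable; the floor is this
  package's declared choice.
* **Gaussian-mixture posterior (LDpred-style)** — spike-and-slab prior:
  `beta_j ~ N(0, h²/(Mp))` with probability `p`, else 0, on the
  standardized scale. Marginal GWAS effects convert to that scale through
  the t statistic (`r = t/sqrt(df + t²)`), so no phenotype variance needs
  to travel with the summary statistics; posterior-mean weights
  back-transform through `sd_y/sd_x`. The Gibbs sweep residualizes each
  marginal effect against the current state through the LD matrix, samples
  inclusion from the exact posterior odds, and samples the effect from the
  conjugate normal `N(v N b̃_j, v)`, `v = 1/(N + 1/sigma²)`; these
  conditionals are exact for the individual-level Gaussian model, and the
  test suite verifies the sampler's stationary distribution against
  brute-force enumeration of all 2^M inclusion patterns at M = 5. The LD
  reference matrix comes from at most 10,000 training samples and is shrunk
  toward the identity by 0.01 for chain stability (set to 0 in the
  exactness tests); defaults are 500 sweeps with 100 burn-in. The (h², p)
  grid — default h² in {0.01, 0.03, 0.1, 0.3} (extensible around an
  external heritability estimate via `with_h2_anchor`), p in {1e-4, 1e-3,
  1e-2, 0.1, 0.3, 1} — is scored by validation Pearson r, with the full
  training cohort as the validation set in the benchmark, mirroring the
  reference protocol. A diverging chain (non-finite state) drops its grid
  point with a log entry. The original software's large default option grid
  is replaced by this explicit config grid; h² is treated purely as a grid
  hyperparameter (no LD-score regression).
* **MLP** — a deliberately minimal numpy feed-forward network (each neuron
  a weighted linear sum plus activation), trained by full-batch Adam on
  squared loss with deterministic seeding; intended for CA-scale variant
  sets. Empty `hidden_sizes` collapses it to a linear model and identity
  activations make the whole map linear — both verified against OLS. Its
  fitted function is generally not a weighted dosage sum, so it exposes the
  same `predict` interface instead of a `PGSModel`; this is the one
  estimator that cannot round-trip a scoring file. Architecture search
  (genetic algorithms, CNNs) is out of scope.

Genotypes are standardized (mean 0, unit variance per variant) before
EN/BR/mixture fitting — the penalties and priors are scale-sensitive — and
weights are always returned on the per-dosage scale the exchange format
requires.

## Evaluation, stratification, sex interaction

The benchmark partitions the training cohort into 5 random equal portions;
each fold trains on 4 (80%) and is tested on the held-out portion, plus the
whole external cohort. GWAS (for P+T and the mixture model) is re-run
inside each fold on the training portion only, so no summary statistic ever
sees a test sample. Performance is Pearson r between score and adjusted
trait; the mean over the five folds is the headline number, with per-fold
records retained. Fit failures are recorded per cell and the benchmark
continues.

Quantile stratification ranks samples into q near-equal groups (ties broken
deterministically by sample id) plus top/bottom-percent selection. Per
sex-by-quantile group (n ≥ 30, smaller groups skipped with a warning), the
trait-on-age trajectory is a penalized cubic B-spline GAM with the penalty
weight chosen by GCV (statsmodels `GLMGam.select_penweight`), bands are
pointwise fitted ± 1.96 se from the smoother's covariance, and curves are
defined only within the group's observed age range. "GAM" does not pin
down a basis or penalty; penalized cubic regression splines with GCV are
fixed here for reproducibility, and the bands are labelled pointwise
because a simultaneous-band convention was not determinable. A noiseless
trait defeats the penalized IRLS loop (perfect separation), in which case
the unpenalized basis regression — which reproduces the data exactly — is
used with correspondingly degenerate bands.

The sex-interaction model is `y = b0 + b1·PGS + b2·Sex + b3·PGS·Sex` with
the PGS standardized to unit variance and `y` adjusted for age and the 10
PCs but *not* for sex, which enters the model itself. Two-sided t p-values
per coefficient; the family threshold again belongs to the realized number
of traits tested.

## Disease scoring and the correlation scan

Disease models filter external-style summary statistics in order: overlap
with the reference panel, LD thinning at r² < 0.9 (note: distinct from the
0.5 used for trait variant-set expansion), INFO > 0.4, MAF > 1% (strict
inequalities as conventionally printed), and exclusion of strand-ambiguous
A/T and G/C SNPs; published betas/log-odds are used verbatim, and
per-filter attrition is recorded in the model provenance. Duplicate
variant records resolve to the highest INFO score (ties keep the first
occurrence — deterministic and order-stable). Indels are unsupported;
variants are SNPs.

Scoring substitutes `2 × effect-allele frequency` — the Hardy-Weinberg
expected dosage — for missing genotype calls. The convention "the
frequency was used in its place" is ambiguous between `f` and `2f`; the
diploid-expectation reading is implemented. Final scores standardize to
mean 0, SD 1 across samples, exactly (to 1e-12 in the tests).

The correlation scan residualizes every score on an intercept + 10 PCs and
tests all trait-by-disease Pearson correlations with t-reference p-values
and a Bonferroni threshold of `0.05 / (n_traits × n_diseases)`. This is a
correlation of scores across samples, not an LD-score genetic correlation.
The synthetic twin plants a disease architecture sharing a chosen fraction
of causal variants with the trait; score-score correlation is then
monotone in that overlap, reaching the product of the two scores'
reliabilities at full overlap.

## Numerical choices and degenerate inputs

- Missing dosages: mean imputation (per-variant mean of observed calls),
  which preserves column means exactly; a fully missing variant errors by
  name. Scoring paths refuse unimputed genotypes rather than guessing.
- Zero-variance variants: GWAS flags them (beta 0, p 1); pairwise r² marks
  their rows NaN; the interaction scan and LD thinning treat degenerate
  columns as redundant.
- Collinear joint models in stepwise selection drop the latest-added
  variant with a warning; collinear covariate matrices error, naming the
  offending columns via pivoted QR.
- The PLINK .bed codec is written in-package (variant-major, 2-bit, A1
  dosage); only hard calls round-trip through .bed, fractional dosages
  live in memory. INFO and missing-rate travel in a sidecar
  `<prefix>.variant_meta.tsv` because .bim has no such columns.
- All stochastic operations take explicit seeds; identical seeds reproduce
  cohorts, fits and benchmarks bit-for-bit.

## Problem sizes

The shipped tests and the acceptance script run on desk-scale instances
chosen to make their statistical assertions sharp but cheap: cohorts of
1,500–10,000 samples, panels of 240–2,000 variants, 10–20 replicate studies
for method-ranking and recovery claims, 200 replicates for coverage and
family-wise-error checks. The method-comparison study uses 10 cohorts of
n = 5,000 training / 2,000 external samples over m = 2,000 variants in LD
blocks (latent r 0.8) with 40 causal variants (20% low-MAF) at h² = 0.3.
The acceptance script's single end-to-end study uses n = 4,000/2,000 over
the same panel shape.

## Known limitations

- The threshold LD model has no recombination-distance decay, no MAF-LD
  coupling beyond thresholding attenuation, and no long-range LD; thinning
  and window logic are exercised by raising the block correlation, not by
  realistic maps.
- PCs are noise by default, so PC adjustment is tested for harmlessness,
  not for stratification correction.
- Passing tests certify the pipeline's statistical machinery under this
  generator; transfer to real cohorts additionally depends on imputation
  error, relatedness, and ancestry structure, all out of scope here.
- The mixture sampler is the plain (non-sparse) variant; no X-chromosome
  conventions; no VCF/BGEN ingestion.
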