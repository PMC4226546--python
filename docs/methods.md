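# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the problem sizes at which the test suite and
`scripts/acceptance.py` exercise them.

## The family design and the synthetic generator

The generator emulates a two-study family design with six family types:
MZ-twin, DZ-twin, adoptive two-offspring, biological two-offspring, mixed
(one biological, one adopted offspring), and step-parents treated as
one-person families.  A full family has four roles (father, mother,
offspring1, offspring2); real cohorts of this kind have many partial
families, so each type carries member-presence probabilities whose defaults
reproduce per-type mean family sizes of roughly 3.45 (MZ), 3.31 (DZ), 1.30
(adoptive), 2.57 (biological), 1.91 (mixed), and 1 (step-parent).  At
one-tenth of the emulated study's family counts this yields ~710
individuals in 237 families, the scale used throughout the tests.

**Genotypes.**  Founders (parents, adoptees, step-parents) draw two
haplotypes from a population model: within blocks of `ld_block_size` SNPs a
latent Gaussian AR(1) with coefficient 0.8 is thresholded to give each SNP
its allele frequency (uniform on `maf_range`, default 0.05–0.5), producing
LD that decays with distance inside blocks and vanishes across block
boundaries.  Biological offspring receive one haplotype per parent with
blocks transmitted intact and free recombination between blocks; MZ
co-twins are genetically identical; adoptees are founders unrelated to
their rearing family.  Missing hard calls are injected completely at
random.  This reproduces the relatedness structure the analyses assume
(GRM entries ≈ 1 for MZ pairs, ≈ 0.5 for first-degree biological pairs,
≈ 0 for adoptive pairs) but not realistic human LD maps, allele-frequency
spectra, or X/mitochondrial inheritance — tests passing here speak to the
statistical machinery, not to properties specific to real human genomes.

**Dosages.**  The imputation R² of an untyped SNP is the ratio of its
dosage variance to the true genotype variance.  The generator realizes a
target R² exactly by mixing: each individual's dosage is the true genotype
with probability R², otherwise the population mean dosage 2f.  This gives
Var(d) = R²·Var(g) and corr(d, g) = √R² identically and keeps dosages in
[0, 2]; it produces a discrete dosage distribution rather than the
continuous posterior means of real imputation software, which is immaterial
to everything downstream (dosages enter regressions as continuous
covariates).  Imputed copies are placed midway between their source SNP and
the next typed position.

**Phenotype.**  y = additive causal-SNP score (variance h²) +
rearing-family shared deviate (variance c², shared by all members of a
family including adoptees and parents) + unique residual, standardized and
then scaled to mean 100 / SD 15, plus sex (default +1 point for females)
and birth-year (default −0.09 points/year) covariate effects.  Shared
environment follows the *rearing* family, not biology — this is precisely
the confound the relatedness-cutoff sweep demonstrates.  The true
intra-family environmental correlation magnitudes of real cohorts are
unknown; c² is a free parameter (tests use 0.2–0.4).

## FGLS engine

The residual covariance is parameterized by role variances and six
relationship correlations (spouse, biological and adoptive
parent–offspring, MZ co-twin, biological and adoptive sibling) shared
across family types; families with missing members use principal
submatrices of their type's block.  Parameters are fit by maximum
likelihood (L-BFGS on log-variances and scaled-arctanh correlations),
alternating with GLS coefficient estimation until the log-likelihood
changes by less than 1e-6 (max 100 iterations).

Two robustness choices matter at small n and are deliberate deviations from
a fully saturated parameterization:

* **Role variances are pooled across family types** (father, mother,
  offspring, singleton) by default.  Per-type variances
  (`var_by_type=True`) leave cells with a handful of observations (e.g.
  mixed-family fathers) unidentifiable; in experiments their estimates
  ranged from 0.2× to 5× the truth and deflated the null scan to λ ≈ 0.62.
  With pooling the 20k-SNP null scan gives λ = 1.00 and empirical size
  0.049 at α = 0.05.
* **Sparse cells are tied, and correlations bounded.**  A role class with
  fewer than 10 observations ties to the best-populated variance parameter
  (a lone step-parent in a validation fold would otherwise drive its
  variance to zero and the whitened design to singularity), and
  correlations are kept inside ±0.99.

The scan ("rapid" FGLS) whitens y, X and all complete-call SNP columns once
with the covariates-only covariance and computes each SNP's coefficient by
Frisch–Waugh projection; SE² is the plug-in (X′V⁻¹X)⁻¹ entry and p comes
from the t reference on n − p − 1 df.  SNPs with missing calls are handled
exactly, by per-family principal-submatrix solves on the observed rows.
The full re-estimated variant (`run_gwas_full`) is the reference: on
well-identified designs the two agree to a few percent in p for SNPs
explaining < 1% of variance, the regime in which the approximation is
intended; for stronger SNPs (easily reached at desk-scale n with the most
extreme of hundreds of null draws) the re-estimated covariance genuinely
moves and so do the p-values.

HWE exact tests and allele frequencies are computed on founders only, since
relatives distort both.  λ is reported, never applied as a correction.
Power uses the noncentral-χ²₁ approximation with ncp = n·q²/(1−q²).

## Gene tests

Genes map to SNPs by 1-based inclusive containment (configurable flank,
default 0); a SNP may belong to several overlapping genes.  The empirical
p-value is (1 + #{T_null ≥ T_obs})/(1 + n_sims) under a staged schedule
10³ → 10⁴ → 10⁵ → 10⁶ that escalates while the estimate sits within 10× the
resolvable floor, bounding runtime while resolving small p.  Sample LD
matrices from few reference individuals can be indefinite; they are
repaired by eigenvalue clipping at 1e-8 and diagonal renormalization.

## Polygenic scoring

Folds are whole families, stratified by family type via shuffled
round-robin (types with fewer than k families are pooled into one stratum).
Scores are weighted sums (not averages); missing genotypes contribute
2·(calibration allele frequency)·w.  Only typed SNPs enter scoring.  Buse's
R² uses the validation subsample's own covariates-only FGLS fit for both
the residualized phenotype and the weight matrix V; Nagelkerke's R² and the
squared Pearson correlation are reported alongside.  The parametric
bootstrap re-fits the covariance model within each simulated calibration
and validation subsample, mirroring the real-data procedure (a switch to
re-use the original fit is the natural alternative; re-fitting is the
default because each bootstrap replicate is meant to traverse the entire
pipeline).

## GREML

The GRM standardizes columns by sample mean/SD (z-scores); allele-frequency
scaling √(2f(1−f)) is available as an option.  Missing calls are handled
pairwise with per-pair SNP counts.  Pruning is greedy: repeatedly drop the
individual with the most over-cutoff pairs (ties to the earlier id);
maximal-retained-set selection is NP-hard and this deterministic heuristic
matches common practice.  REML works in the eigenbasis of A (V is diagonal
there), takes one EM step, then average-information updates with step
halving; convergence at |Δ log-likelihood| < 1e-6, components floored at
1e-6·var(y), SEs from the inverse AI matrix, h² SE by the delta method.
eBLUPs are ĝ = σ̂²_g A V̂⁻¹(y − Xβ̂); their QQ plots should be read
cautiously since the predictions are shrunken toward the normal prior they
assume.

## Problem sizes and tolerances

Desk-scale sizes were chosen so each check is statistically decisive yet
the whole suite runs in minutes on one CPU:

* Null-scan calibration: 710 individuals / 237 families, 20,000 independent
  SNPs, c² = 0.3; empirical size judged against the binomial 95% interval
  and λ against [0.95, 1.05].
* Gene-test oracles: 10⁵ null draws against the χ²_m and m·χ²₁ closed
  forms (KS p > 0.01); the single-SNP gene at 2×10⁵ draws.
* GREML: n = 2,000 unrelateds × 5,000 SNPs (GRM noise SD ≈ 0.014, SE(ĥ²)
  ≈ 0.05); recovery at h² ∈ {0, 0.35, 0.5} judged at 2·SE over 5 replicate
  traits (majority rule), coverage over 50 replicates.
* Cutoff sweep: 500 complete families (adoptive-rich) × 30,000 SNPs so the
  GRM noise (SD ≈ 0.006) sits well below the 0.025 cutoff; 10 replicates,
  h² = 0.3, c² = 0.4.
* Polygenic scoring: 296 families (~880 individuals), 2,000 SNPs with
  1,000 causal, h² = 0.5, c² = 0.2; 5-fold CV and a 50-iteration bootstrap
  null.

## Known limitations

* The generator's LD is block-wise AR(1), not a coalescent or reference
  panel; gene-test Σ matrices are therefore tamer than real ones.
* The covariance parameterization assumes correlations shared across family
  types; a saturated per-type structure is available but needs far more
  families than desk scale provides.
* The rapid-FGLS approximation degrades for SNPs explaining ≳1% of
  variance; at real cohort sizes this is immaterial, at desk scale it is
  visible in the extreme tail.
* Binary traits, gene–environment interaction, multi-component or bivariate
  GREML, LD clumping before scoring, and genomic-control correction are out
  of scope.
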