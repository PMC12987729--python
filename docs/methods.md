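# Methods

This note records the models, conventions and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Species quantification from signature genes

A species' relative abundance is estimated from its signature genes only:
species-unique core genes between 200 bp and 20 kb, at most 250 per species,
selected from pangenomes by prevalence (≥60% of the species' MAGs), length
window and a precomputed uniqueness flag. When more genes are eligible than
the cap, the priority is higher prevalence, then longer gene, then
lexicographic id — the tie-break is a convention, chosen only so selection is
deterministic. Species with fewer than 20 eligible genes are flagged
`fallback_needed`; the segment-masking fallback used for such species in
production profilers is out of scope here.

**Read-pair counting.** A read is uniquely mapped when MAPQ ≥ 20, identity
≥ 95% over ≥ 100 aligned bp, and ≤ 10 bases fail to align; identity/length
without the MAPQ threshold makes it multi-mapped. A pair counts toward a gene
if either read is uniquely mapped (read one's gene wins when both are), is
multi-mapped if no read is unique but one is multi-mapped, and unmapped
otherwise. All comparisons are inclusive at the stated boundaries.

**Count model.** Conditional on a species' total signature count T in a
sample, gene g's count is negative binomial with mean μ_g = T·L_g/ΣL and size
r_g = log2(L_g), where L is the *effective* length. Two conventions to note:

- "Dispersion" is taken to be the NB size parameter r (Var = μ + μ²/r).
  r is floored at 1 so very short genes cannot produce a degenerate model.
- Effective length is L_eff = max(L − 100 + 1, 1), the number of valid
  alignment start positions under the 100-bp alignment criterion. The
  constant is configurable (`catalog.MIN_ALIGN_LEN`).

**Filtering rules**, per species per sample, in order:

1. *Zero-ignoring.* If ≥50 signature genes are non-zero and the model,
   evaluated at the species total over all signature genes, expects ≥99% of
   genes to be non-zero (mean over genes of P(X_g > 0) ≥ 0.99), zero-count
   genes are treated as artefacts and dropped from the considered set. The NB
   means are then rescaled over the retained genes; the denominator is a
   convention the source rules leave open.
2. *Quantile filter.* Counts outside the inclusive [0.5%, 99.5%] NB quantiles
   are outliers and excluded. Inclusivity at the bounds is a convention.
3. *Abundance* = mean over admitted genes of count/L_eff.
4. *66% rule.* If fewer than 66% of the considered genes are non-zero within
   bounds, the species is zeroed unless the median count/L_eff over all its
   signature genes is positive, in which case the median over non-zero genes
   replaces the mean. This rule is evaluated *before* the <5-gene rule: the
   median fallback is what keeps the estimator stable when contamination
   inflates the species total and thereby distorts every gene's bounds, and
   an implementation that zeroes first can never be rescued by it.
5. *<5 rule.* If fewer than five admitted genes are non-zero, the species is
   zeroed.
6. *Closure.* Rows are renormalized to 100%; empty samples stay at 0.

The denominator of the 66% rule is the considered set after zero-ignoring.

**Rarefaction** draws a fixed number of signature read pairs per sample
without replacement (multivariate hypergeometric); samples below the target
are excluded and flagged rather than erroring, matching cohort-QC practice.
The default target is 164,245 read pairs. Shannon diversity uses the natural
logarithm. The prevalence filter for downstream association analysis keeps
species (or modules) with abundance > 0 in ≥30% of samples.

**KO and module profiles.** Gene abundance is count/L_eff over *all* catalog
genes; a KO's value is its abundance share of the total (unannotated
abundance dilutes the KO sums, which therefore need not reach 1). Module
association requires ≥2/3 of the distinct KOs of some path (KO-weighted, not
step-weighted — recorded per association for audit), with every step covered
for paths of ≤3 steps. Module abundance is the sum of associated species'
relative abundances.

## Association

Traits are inverse rank-normal transformed with the Blom offset 3/8 (average
ranks for ties); the offset choice is conventional and immaterial at cohort
sizes. Single-variant tests are OLS of the transformed trait on dosage plus
covariates. A whole-genome ridge / mixed-model step, used in production GWAS
to absorb relatedness and polygenic background, is deliberately not
implemented: the generator produces unrelated samples, for which the OLS
estimand is identical. Variants with MAF < 1% are excluded. Two-sided
p-values use the normal approximation for n ≥ 1000 and Student's t below.
Conditional scans add each index SNP to the covariates and stop when no
remaining variant beats the entry threshold; conditioned SNPs leave the scan
(their own residual test is degenerate).

Meta-analysis follows the METAL conventions: fixed-effect IVW on (β, se), or
sample-size weighting of signed z-scores, z = Σz_i√n_i/√Σn_i, which is the
required method when effect sizes are on incompatible trait scales (the IVW
path refuses mixed scales). The effective number of tests uses the Li–Ji
eigenvalue rule, M_eff = Σ[1(λ≥1) + frac(λ)] over the trait correlation
spectrum; because published effective-test counts depend on the exact cohort,
`study_wide_threshold` accepts an explicit M_eff override so printed
thresholds are reproducible from the reported count alone. Replication
requires a concordant, non-zero effect direction and p < 0.05/k.

Logistic association returns the OR per s.d. of exposure (Wald CI); perfect
separation raises with a diagnostic. Partial Spearman correlations rank both
variables, residualize on covariates, and use a t-test with n−2−k degrees of
freedom.

## Heritability

The GRM is the standard allele-frequency-standardized estimator; monomorphic
SNPs are excluded and counted. REML is single-component average-information
with an EM fallback whenever the AI update fails or leaves the parameter
space, variance components floored at 1e-6·Vp, convergence at |Δ log L| <
1e-6, at most 100 iterations, and standard errors from the inverse AI matrix
(delta method for h²). Because only one GRM enters the model, all REML
quantities are computed in the eigenbasis of A: one O(n³) eigendecomposition,
then O(n²) per iteration. Non-convergence is flagged on the result rather
than raised. Haseman–Elston regression (pairwise trait cross-products on
off-diagonal relatedness) provides a moment-based cross-check; its slope
estimates h² directly for a standardized trait. A greedy GRM-threshold pruner
(drop one of any pair with A_jk > 0.05) is provided for parity with
kinship-based QC; the synthetic cohorts are unrelated, so it is a no-op
there. Note that with sample-frequency centering the off-diagonals of an
unrelated GRM concentrate around −1/(n−1), so the pruner is meaningful only
for n well above ~50.

## Mendelian randomization and colocalization

Instrument selection: MAF > 1%, exposure p < 5×10⁻⁸, then greedy pruning in
ascending p-order dropping any variant with r² ≥ 0.01 (squared dosage
correlation in the supplied panel) against a retained one. Per-instrument
R² = 2p(1−p)β² / Var(trait) and F = R²(n−2)/(1−R²).

Estimators: Wald ratio with first-order delta s.e. (exposure uncertainty
beyond first order ignored); IVW as weighted regression through the origin
with weights se_out⁻²; the `auto`/`ivw` mode switches to multiplicative
random effects, se × max(1, √(Q/(k−1))), when Cochran's Q has p < 0.05 — the
trigger and the multiplicative form are this package's choices, since
"depending on Q" admits several conventions. MR-Egger orients exposure
effects positive, fits a weighted intercept+slope regression with
overdispersion floored at 1, and reports the intercept as the directional-
pleiotropy diagnostic. The weighted median uses the standard interpolated
weighted quantile with a parametric bootstrap s.e. (1000 resamples, seeded).
IVW with a single instrument reduces exactly to the Wald ratio.

The many-trait screen compares the observed count of nominal (p < α) MR
results with the expected α·n via a 1-df chi-square on the significant /
non-significant split, and reports an exact binomial p alongside: the 1-df
statistic from (observed, expected) alone does not pin down every published
variant of this test, so both are exposed. The screen also reports the
Pearson correlation between observational betas and MR betas.

Colocalization: per-variant Wakefield log-ABFs, ½[log(1−r) + r·z²] with
r = W/(V+W), prior effect variance W = 0.15² for quantitative and 0.2² for
binary traits, combined in log space into the five hypothesis sums with
priors (p1, p2, p12) = (1e-4, 1e-4, 1e-5); all priors are configurable.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
raw sequence data (no FASTQ, no alignment, no reference-panel LD):

- *Compositions.* Species baselines are log-normal (between-species s.d. 1.5,
  heavy-tailed like real communities); samples add independent log-normal
  noise (s.d. 1.0) and compositions are obtained by closure. The unit
  within-species s.d. makes the latent log scale and the IRNT trait scale
  coincide, so planted per-allele effects are recovered nearly 1:1.
- *Counts.* Reads recruit per base pair community-wide: gene g's NB mean is
  depth · comp(s, sp(g)) · L_g normalized by the composition-weighted total
  signature length of the sample, so a sample's signature genes total `depth`
  in expectation and the profiler's mean(count/L) estimator is unbiased for
  composition. The default depth of 1.3M signature read pairs per sample
  follows from typical stool sequencing arithmetic (~23M read pairs, ~84%
  mapped, signature genes a few percent of the catalog) and comfortably
  contains the 164,245 rarefaction target. Outlier cells (fraction
  `outlier_gene_rate`, fold `outlier_fold`) emulate genes that spuriously
  recruit reads.
- *Genotypes.* Biallelic, HWE, MAF uniform in `maf_range`; within an LD block
  consecutive SNPs copy the previous SNP's haplotypes with resample
  probability 0.1 — enough LD structure for pruning and colocalization tests,
  not a realistic decay curve.
- *Effects.* SNP and BMI effects add to latent log abundance before closure.
  Closure attenuates recovered betas by roughly 5–10% at the default
  community sizes (measured, not assumed); planted |β| of 0.05–0.19 per
  allele mirror the magnitude range of replicated host–microbiome signals.
  Covariates (age, sex, plate) carry small effects so adjustment is
  non-trivial. Disease status is Bernoulli from a logistic model on one
  species' standardized latent abundance.
- *Cohort pairs* share the catalog, SNP panel and effect table but draw all
  noise independently, with disjoint prefixed sample ids.
- *Coloc panels* regress both traits on raw genotypes variant-by-variant, so
  the emitted summary statistics are exactly what a GWAS of the raw data
  would produce (checked against an independent OLS oracle).
- *MR summary data* are generated at the summary level: instrument effects
  gamma ~ |N(0.02, 0.02²)|+0.005 with GWAS-scale standard errors at
  n_exposure = 300k and n_outcome = 12,652.

Passing tests therefore demonstrate correctness of the estimators under
their own modelling assumptions — unbiased composition recovery, calibrated
nulls, recovery of planted effects — not robustness to the many features of
real data the generator omits: compositional zero-inflation beyond the NB
model, strain-level gene content variation, batch effects, population
stratification and relatedness, realistic LD, and assay noise in covariates.

## Problem sizes and numerical conventions

The test suite and acceptance script use deliberately modest problem sizes
chosen as the smallest at which each property is sharply testable: profiler
recovery on 200 samples × 50 species, GWAS recovery at n = 20,000, GREML at
n = 1,500 / m = 2,000, MR with k = 30 instruments, screens of 546 traits with
200 null replicates, coloc regions of 50 variants at n = 2,000. Tolerances
follow the estimators' own standard errors (2 s.e. for recovery checks,
binomial 99% bands for calibration checks, 1e-10..1e-12 for algebraic
oracles). Degenerate inputs are defined rather than crashed on: zero totals
give zero bounds and empty profiles, depth 0 gives an all-zero count table,
empty instrument sets are returned (estimators then refuse), and REML
non-convergence is a flag.

## Known limitations

No mixed-model association, X chromosome, imputation INFO handling,
LD-score-regression heritability, multi-component GREML, MR-PRESSO/radial or
multivariable MR, or LD-aware (SuSiE-style) colocalization. The KEGG module
criterion weights by KO, not by step, where the two differ. The
segment-masking fallback for species with few unique genes is not
implemented. These are scope decisions, not oversights.
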