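# microgwas

A reusable pipeline for host-genetics studies of the gut microbiome: it takes
per-gene metagenomic read counts to species and functional profiles, runs
covariate-adjusted GWAS of those profiles with meta-analysis and replication
decisions, estimates SNP heritability, and follows up with two-sample
Mendelian randomization and Bayesian colocalization. A synthetic-data
generator produces every input with known ground truth, so each stage is
validated end-to-end without any external data.

It is written for statistical geneticists and microbiome researchers who want
the quantitative core of a microbiome GWAS — the profiling rules, the
association arithmetic, the causal follow-up — as tested, scriptable Python.

## Methods at a glance

**Species profiling.** Each species is quantified from up to 250 *signature
genes* (species-unique core genes, 200 bp–20 kb). Given a species' total
signature read count T in a sample, gene g's count is modelled as negative
binomial with mean μ_g = T·L_g/ΣL (L = effective gene length) and size
r_g = log2(L_g), so Var = μ + μ²/r. Counts outside the central 99% of that
distribution (quantiles 0.5%–99.5%) are treated as outliers; abundance is the
mean of count/L over admitted genes, with zero-ignoring, a <5-gene zero rule
and a median fallback for species with <66% of genes in bounds, then
sample-wise closure to 100%. α-diversity (Shannon, −Σp·ln p, and richness) is
computed on profiles rarefied without replacement. KO profiles are
length-normalized abundance proportions; a species is associated with a KEGG
module when ≥2/3 of some path's KOs are present (all steps required for
modules of ≤3 steps), and module abundance is the sum over associated
species.

**Association.** Traits are inverse rank-normal transformed
(Φ⁻¹((r−3/8)/(n+1/4))) and tested per SNP by covariate-adjusted OLS under an
additive model (MAF ≥ 1%), with stepwise conditional scans, a SNP×SNP
interaction test, METAL-style fixed-effect IVW (β̂ = Σwβ/Σw, w = se⁻²) and
sample-size-weighted meta-analysis, Li–Ji effective-test thresholds
(α_gw/M_eff), and Bonferroni replication decisions (concordant sign and
p < 0.05/k).

**Heritability.** A GCTA-style GRM, A_jk = m⁻¹Σ_i (x_ij−2p_i)(x_ik−2p_i) /
2p_i(1−p_i), feeds single-component AI-REML for y = Xb + g + e with
Var(g) = A·Vg; h² = Vg/(Vg+Ve), with Haseman–Elston regression as a
moment-based cross-check.

**Causal follow-up.** Instruments are independent (r² < 0.01), common
(MAF > 1%), genome-wide-significant (p < 5×10⁻⁸) variants. Wald ratio for a
single instrument; IVW through the origin with Cochran's-Q-dependent
fixed/random effects; MR-Egger and the weighted median as sensitivity
analyses; a many-trait screen summarised by the observed vs expected (α·n)
nominal-hit count and the correlation of observational and MR betas.
Colocalization uses per-variant Wakefield approximate Bayes factors combined
into posteriors over H0–H4 with priors (1e-4, 1e-4, 1e-5).

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
cohorts and write their tables under `results/`:

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_profile_community.py
python analysis/03_gwas_meta_replication.py
python analysis/04_heritability.py
python analysis/05_mr_and_coloc.py
```

Step 02 prints, for 120 simulated samples of a 30-species community
sequenced at 1.3M signature read pairs:

```
profiled 120 samples x 30 species; 30 species at prevalence >= 30%
recovery vs truth (cells >= 0.5% abundance): mean |rel err| 1.8%, max 8.9%
rarefied to 164,245 signature read pairs (0 samples excluded); Shannon 2.23 +/- 0.29, richness 22.6
```

i.e. the NB-filtered profiler recovers every cell of the true composition to
within 10% relative error for species above 0.5% abundance. Step 03 then
recovers the planted per-allele genetic effects and makes replication calls:

```
rs00009 -> sp004: planted -0.14, discovery -0.149 (p=3.3e-06), replication -0.150 (p=2.8e-09), meta -0.150, replicated
effective tests across 30 species: M_eff = 28.0; study-wide threshold 1.8e-09
```

Step 04 reports AI-REML and Haseman–Elston heritability for planted
h² ∈ {0, 0.1, 0.3} (e.g. `planted h2=0.30: REML 0.350 +/- 0.044, HE 0.371 +/-
0.042`), and step 05 prints the MR estimates, the 546-trait screen summary
and the colocalization posteriors (PP4 ≈ 1 for a shared causal variant,
PP3 ≈ 1 for distinct ones, PP0 ≈ 1 under the null).

A `microgwas` console script exposes the same stages (`simulate`, `profile`,
`gwas`, `meta`, `replicate`, `mr`, `screen`, `coloc`) for ad-hoc runs on
exported tables; see `microgwas --help`.

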