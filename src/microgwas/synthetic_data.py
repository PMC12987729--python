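"""Synthetic cohort generator with known ground truth.

Every input the pipeline consumes can be generated here: a gene catalog with
signature genes and KO annotations, KEGG module definitions, per-sample
per-gene read count tables drawn from the profiler's negative-binomial model
(with optional planted outlier genes), biallelic genotypes in Hardy-Weinberg
equilibrium with optional LD blocks, host covariates, a BMI-like trait,
a binary disease phenotype, planted additive SNP -> species effects on the
latent log-abundance scale, paired discovery/replication cohorts, and paired
summary-statistic panels for colocalization.

The latent composition model is log-normal: each species has a fixed baseline
log-abundance drawn once per catalog seed, each sample adds independent
log-normal noise, genetic and BMI effects act additively on the latent log
scale, and compositions are obtained by closure (softmax).  Because of the
closure, a planted per-allele effect beta is recovered on the IRNT scale only
approximately (attenuated by the renormalization); the attenuation is small
when individual species are rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import (
    GeneCatalog,
    KeggModuleDef,
    SIGNATURE_GENE_CAP,
    SIGNATURE_MAX_LENGTH,
    SIGNATURE_MIN_LENGTH,
    effective_length,
)
from .profiling import nb_size


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


@dataclass
class SnpEffect:
    """Planted additive effect of one SNP on one species (per effect allele,
    on the latent log-abundance scale)."""

    snp: str
    species: str
    beta: float


@dataclass
class DiseaseModel:
    """Logistic disease model: logit P(case) = intercept + slope * z(species),
    where z is the standardized latent log abundance."""

    species: str
    intercept: float
    slope: float


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the package's study conditions.

    ``depth`` is the expected number of signature-gene read pairs per sample.
    ``effect_table`` lists planted per-allele SNP effects whose magnitudes
    (|beta| 0.05-0.19 s.d.) mirror replicated host-genetics signals for gut
    species; ``bmi_effects`` maps species to the causal effect of a BMI-like
    trait on latent log abundance.
    """

    seed: int = 0
    n_samples: int = 200
    n_species: int = 50
    genes_per_species: int = 300
    depth: float = 1_300_000.0
    outlier_gene_rate: float = 0.0
    outlier_fold: float = 50.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_snps: int = 100
    ld_block_size: int = 1
    effect_table: list[SnpEffect] = field(default_factory=list)
    bmi_effects: dict[str, float] = field(default_factory=dict)
    disease_model: DiseaseModel | None = None
    # latent composition model; unit within-species sd makes the latent and
    # IRNT trait scales coincide, so planted per-allele betas are recovered
    # up to the (documented) closure attenuation
    species_log_sd: float = 1.5     # between-species spread of baselines
    sample_log_sd: float = 1.0      # within-species between-sample noise
    n_kos: int = 40
    ko_fraction: float = 0.6        # fraction of genes carrying a KO label

    def __post_init__(self):
        if self.n_samples < 1 or self.n_species < 1 or self.genes_per_species < 1:
            raise ConfigError("n_samples, n_species and genes_per_species must be >= 1")
        if self.depth < 0:
            raise ConfigError("depth must be >= 0")
        if not 0.0 <= self.outlier_gene_rate <= 1.0:
            raise ConfigError("outlier_gene_rate must be in [0, 1]")
        if self.outlier_gene_rate > 0 and self.outlier_fold <= 1:
            raise ConfigError("outlier_fold must be > 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if self.n_snps < 1:
            raise ConfigError("n_snps must be >= 1")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")

    def species_ids(self) -> list[str]:
        return [f"sp{i:03d}" for i in range(self.n_species)]

    def snp_ids(self) -> list[str]:
        return [f"rs{i:05d}" for i in range(self.n_snps)]


def _rng(config_seed: int, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generator stage."""
    return np.random.default_rng(np.random.SeedSequence([config_seed, stream]))


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    sample_ids: list[str]
    species_ids: list[str]
    latent_log: np.ndarray            # samples x species, before closure
    effect_table: list[SnpEffect] = field(default_factory=list)
    bmi_effects: dict[str, float] = field(default_factory=dict)
    coloc_causal: dict[str, int] = field(default_factory=dict)

    @property
    def true_compositions(self) -> pd.DataFrame:
        """Samples x species fractions, rows summing to 1 (closure of the
        latent log abundances)."""
        z = self.latent_log - self.latent_log.max(axis=1, keepdims=True)
        w = np.exp(z)
        return pd.DataFrame(
            w / w.sum(axis=1, keepdims=True), index=self.sample_ids, columns=self.species_ids
        )


# ---------------------------------------------------------------------------
# Catalog + module definitions
# ---------------------------------------------------------------------------

def generate_catalog(config: SimConfig) -> tuple[GeneCatalog, list[KeggModuleDef]]:
    """Generate a gene catalog and KEGG module definitions.

    Per species, ``genes_per_species`` genes with log-normal lengths; the
    first ``min(genes_per_species, 250)`` are signature genes with lengths
    clipped to [200, 20000] bp.  Each gene carries zero or one KO from a
    shared pool; module definitions reference only generated KOs.
    """
    rng = _rng(config.seed, 1)
    ko_pool = [f"K{i:05d}" for i in range(config.n_kos)]
    rows = []
    n_sig = min(config.genes_per_species, SIGNATURE_GENE_CAP)
    for s, sp in enumerate(config.species_ids()):
        lengths = np.clip(
            rng.lognormal(mean=np.log(1500), sigma=0.8, size=config.genes_per_species).astype(int),
            SIGNATURE_MIN_LENGTH,
            SIGNATURE_MAX_LENGTH,
        )
        has_ko = rng.random(config.genes_per_species) < config.ko_fraction
        # species carry overlapping but distinct KO repertoires
        repertoire = rng.choice(ko_pool, size=max(2, config.n_kos // 2), replace=False)
        kos = np.where(has_ko, rng.choice(repertoire, size=config.genes_per_species), "")
        for g in range(config.genes_per_species):
            rows.append(
                {
                    "gene_id": f"{sp}_g{g:04d}",
                    "species_id": sp,
                    "length": int(lengths[g]),
                    "effective_length": int(effective_length(int(lengths[g]))),
                    "is_signature": g < n_sig,
                    "ko": str(kos[g]),
                }
            )
    catalog = GeneCatalog(pd.DataFrame(rows))

    modules = []
    n_modules = 8
    for m in range(n_modules):
        n_paths = 1 + (m % 2)
        paths = []
        for _ in range(n_paths):
            n_steps = int(rng.integers(2, 7))
            path = []
            for _ in range(n_steps):
                step = rng.choice(ko_pool, size=int(rng.integers(1, 3)), replace=False)
                path.append(frozenset(step.tolist()))
            paths.append(path)
        modules.append(KeggModuleDef(f"M{m:05d}", paths, name=f"synthetic module {m}"))
    return catalog, modules


# ---------------------------------------------------------------------------
# Latent compositions, genotypes, traits
# ---------------------------------------------------------------------------

def generate_truth(config: SimConfig) -> GroundTruth:
    """Baseline latent log abundances (no genetic or BMI effects yet)."""
    rng = _rng(config.seed, 2)
    base = rng.normal(0.0, config.species_log_sd, size=config.n_species)
    noise = rng.normal(0.0, config.sample_log_sd, size=(config.n_samples, config.n_species))
    latent = base[None, :] + noise
    samples = [f"S{i:05d}" for i in range(config.n_samples)]
    return GroundTruth(samples, config.species_ids(), latent,
                       effect_table=list(config.effect_table),
                       bmi_effects=dict(config.bmi_effects))


@dataclass
class GenotypePanel:
    """Dosage matrix (samples x SNPs, counts of the effect allele) plus
    variant metadata (chromosome, position, alleles, generating MAF)."""

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def eaf(self) -> pd.Series:
        return self.dosages.mean(axis=0) / 2.0


_ALLELES = np.array(["A", "C", "G", "T"])


def _simulate_dosages(rng, n_samples: int, mafs: np.ndarray, ld_block_size: int) -> np.ndarray:
    """HWE genotypes; within an LD block consecutive SNPs share haplotypes
    via copying-with-mutation (resample probability 0.1 per haplotype)."""
    n_snps = len(mafs)
    haps = np.empty((n_samples, 2, n_snps), dtype=np.int8)
    for j in range(n_snps):
        fresh = rng.random((n_samples, 2)) < mafs[j]
        if j % ld_block_size == 0:
            haps[:, :, j] = fresh
        else:
            copy = rng.random((n_samples, 2)) >= 0.1
            haps[:, :, j] = np.where(copy, haps[:, :, j - 1], fresh)
    return haps.sum(axis=1)


def generate_genotypes_and_traits(
    config: SimConfig, truth: GroundTruth
) -> tuple[GenotypePanel, pd.DataFrame, GroundTruth]:
    """Genotypes, host covariates and traits; plants effects into ``truth``.

    Planted SNP and BMI effects are added to the latent log abundances before
    closure, so ``truth.true_compositions`` reflects them.  Returns
    ``(panel, traits, truth)`` where ``traits`` has columns age, sex, plate,
    bmi and (if a disease model is configured) disease.
    """
    rng = _rng(config.seed, 3)
    snps = config.snp_ids()
    known_species = set(truth.species_ids)
    for eff in config.effect_table:
        if eff.snp not in snps or eff.species not in known_species:
            raise ConfigError(f"effect_table references unknown snp/species: {eff}")
    if config.disease_model and config.disease_model.species not in known_species:
        raise ConfigError("disease_model references unknown species")

    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    dosages = _simulate_dosages(rng, config.n_samples, mafs, config.ld_block_size)
    ea_idx = rng.integers(0, 4, size=config.n_snps)
    nea_idx = (ea_idx + rng.integers(1, 4, size=config.n_snps)) % 4
    variants = pd.DataFrame(
        {
            "snp": snps,
            "chr": 1 + (np.arange(config.n_snps) % 22),
            "pos": 10_000 + 5_000 * np.arange(config.n_snps),
            "ea": _ALLELES[ea_idx],
            "nea": _ALLELES[nea_idx],
            "maf": mafs,
        }
    ).set_index("snp")
    panel = GenotypePanel(pd.DataFrame(dosages, index=truth.sample_ids, columns=snps), variants)

    n = config.n_samples
    age = rng.uniform(20, 80, size=n)
    sex = rng.integers(0, 2, size=n)
    plate = rng.integers(0, 8, size=n)
    bmi = 25.0 + 0.05 * (age - 50.0) + 0.8 * sex + rng.normal(0, 3.5, size=n)
    z_bmi = (bmi - bmi.mean()) / bmi.std()

    sp_index = {sp: j for j, sp in enumerate(truth.species_ids)}
    latent = truth.latent_log.copy()
    # mild host-covariate effects so adjustment is non-trivial downstream
    z_age = (age - age.mean()) / age.std()
    latent += 0.05 * z_age[:, None] + 0.05 * (sex - 0.5)[:, None]
    for eff in config.effect_table:
        latent[:, sp_index[eff.species]] += eff.beta * dosages[:, snps.index(eff.snp)]
    for sp, beta in config.bmi_effects.items():
        latent[:, sp_index[sp]] += beta * z_bmi
    truth.latent_log = latent
    truth.effect_table = list(config.effect_table)
    truth.bmi_effects = dict(config.bmi_effects)

    traits = pd.DataFrame(
        {"age": age, "sex": sex, "plate": plate, "bmi": bmi}, index=truth.sample_ids
    )
    if config.disease_model is not None:
        dm = config.disease_model
        z_sp = stats.zscore(latent[:, sp_index[dm.species]])
        p_case = 1.0 / (1.0 + np.exp(-(dm.intercept + dm.slope * z_sp)))
        traits["disease"] = (rng.random(n) < p_case).astype(int)
    return panel, traits, truth


# ---------------------------------------------------------------------------
# Read counts
# ---------------------------------------------------------------------------

def generate_counts(catalog: GeneCatalog, truth: GroundTruth, config: SimConfig) -> pd.DataFrame:
    """Per-sample per-gene NB read counts from the profiler's model.

    The expected count of gene g in sample s is proportional to
    composition(s, species(g)) x effective_length(g) x depth, normalized so
    a sample's signature genes total ``depth`` in expectation.  A fraction
    ``outlier_gene_rate`` of gene-sample cells is inflated ``outlier_fold``-x
    (outlier genes the quantile filter must reject).
    """
    if config.depth < 0:
        raise ConfigError("depth must be >= 0")
    rng = _rng(config.seed, 4)
    genes = catalog.genes
    missing = set(genes["species_id"].unique()) - set(truth.species_ids)
    if missing:
        raise ConfigError(f"catalog species missing from truth: {sorted(missing)}")

    comp = truth.true_compositions.to_numpy()
    sp_index = {sp: j for j, sp in enumerate(truth.species_ids)}
    gene_sp = genes["species_id"].map(sp_index).to_numpy()
    L = genes["effective_length"].to_numpy(dtype=float)
    if config.depth == 0:
        return pd.DataFrame(
            0, index=truth.sample_ids, columns=genes["gene_id"].tolist(), dtype=np.int64
        )

    # reads recruit per base-pair community-wide: one normalizer per sample
    # (the composition-weighted total signature length), chosen so a sample's
    # signature genes total `depth` read pairs in expectation
    is_sig = genes["is_signature"].to_numpy()
    norm = (comp[:, gene_sp[is_sig]] * L[is_sig][None, :]).sum(axis=1)
    mu = config.depth * comp[:, gene_sp] * L[None, :] / norm[:, None]
    r = nb_size(L)[None, :]
    p = r / (r + np.maximum(mu, 1e-300))
    counts = rng.negative_binomial(np.broadcast_to(r, mu.shape), p)
    if config.outlier_gene_rate > 0:
        mask = rng.random(mu.shape) < config.outlier_gene_rate
        counts = np.where(mask, np.round(counts * config.outlier_fold).astype(np.int64), counts)
    return pd.DataFrame(counts.astype(np.int64), index=truth.sample_ids,
                        columns=genes["gene_id"].tolist())


# ---------------------------------------------------------------------------
# Cohort pairs
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    name: str
    config: SimConfig
    truth: GroundTruth
    genotypes: GenotypePanel
    traits: pd.DataFrame


def _make_cohort(name: str, config: SimConfig) -> Cohort:
    truth = generate_truth(config)
    panel, traits, truth = generate_genotypes_and_traits(config, truth)
    prefix = f"{name}_"
    truth.sample_ids = [prefix + s for s in truth.sample_ids]
    panel.dosages.index = truth.sample_ids
    traits.index = truth.sample_ids
    return Cohort(name, config, truth, panel, traits)


def generate_cohort_pair(config: SimConfig, replication_n: int | None = None) -> tuple[Cohort, Cohort]:
    """Disjoint discovery/replication cohorts with identical planted effects.

    Sample ids are prefixed by cohort; noise is independent between cohorts;
    the effect table, species and SNP panels are shared.
    """
    if config.n_samples < 1 or (replication_n is not None and replication_n < 1):
        raise ConfigError("cohort sizes must be >= 1")
    disc_cfg = replace(config, seed=int(np.random.SeedSequence([config.seed, 10]).generate_state(1)[0] % 2**31))
    repl_cfg = replace(
        config,
        seed=int(np.random.SeedSequence([config.seed, 11]).generate_state(1)[0] % 2**31),
        n_samples=replication_n if replication_n is not None else config.n_samples,
    )
    return _make_cohort("DISC", disc_cfg), _make_cohort("REPL", repl_cfg)


# ---------------------------------------------------------------------------
# Colocalization panels
# ---------------------------------------------------------------------------

@dataclass
class ColocPanel:
    stats1: pd.DataFrame   # SNP BETA SE P N per variant
    stats2: pd.DataFrame
    ld: np.ndarray         # variant x variant correlation
    causal1: int
    causal2: int | None    # None under the null / single-trait modes
    mode: str


def _marginal_stats(dosages: np.ndarray, y: np.ndarray, snp_ids: list[str]) -> pd.DataFrame:
    """Per-variant simple OLS of y on dosage (the summary statistics a GWAS
    of the raw data would produce)."""
    n = len(y)
    g = dosages - dosages.mean(axis=0)
    yc = y - y.mean()
    gg = (g * g).sum(axis=0)
    beta = g.T @ yc / gg
    rss = (yc * yc).sum() - beta**2 * gg
    se = np.sqrt(rss / (n - 2) / gg)
    z = beta / se
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"SNP": snp_ids, "BETA": beta, "SE": se, "P": p, "N": n,
         "EAF": dosages.mean(axis=0) / 2.0}
    ).set_index("SNP")


def generate_coloc_panel(
    mode: Literal["shared", "distinct", "null"], config: SimConfig, causal_beta: float = 0.5
) -> ColocPanel:
    """Two summary-statistic tracks over one region, for colocalization tests.

    ``shared``: both traits are driven by the same causal variant;
    ``distinct``: by two different variants; ``null``: neither trait has a
    signal in the region.  Summary statistics are computed by per-variant
    regression on the raw simulated genotypes and traits.
    """
    if mode not in ("shared", "distinct", "null"):
        raise ConfigError(f"unknown coloc panel mode: {mode!r}")
    if config.n_snps < 10:
        raise ConfigError("coloc panel needs a region of >= 10 variants")
    rng = _rng(config.seed, 5)
    n, m = config.n_samples, config.n_snps
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    dosages = _simulate_dosages(rng, n, mafs, config.ld_block_size).astype(float)
    snp_ids = config.snp_ids()

    c1 = int(rng.integers(0, m))
    if mode == "distinct":
        c2 = int((c1 + m // 2) % m)
    elif mode == "shared":
        c2 = c1
    else:
        c2 = None

    y1 = rng.normal(0, 1, size=n)
    y2 = rng.normal(0, 1, size=n)
    if mode != "null":
        y1 = y1 + causal_beta * (dosages[:, c1] - dosages[:, c1].mean())
        y2 = y2 + causal_beta * (dosages[:, c2] - dosages[:, c2].mean())

    ld = np.corrcoef(dosages, rowvar=False)
    return ColocPanel(
        _marginal_stats(dosages, y1, snp_ids),
        _marginal_stats(dosages, y2, snp_ids),
        ld,
        c1,
        c2,
        mode,
    )


# ---------------------------------------------------------------------------
# Two-sample MR summary statistics
# ---------------------------------------------------------------------------

def generate_mr_instruments(
    k: int,
    causal_effect: float,
    seed: int,
    n_exposure: int = 300_000,
    n_outcome: int = 12_652,
    gamma_sd: float = 0.02,
    pleiotropy_sd: float = 0.0,
    pleiotropy_mean: float = 0.0,
) -> pd.DataFrame:
    """Summary-level two-sample MR system with a planted causal effect.

    Each of ``k`` independent instruments has a true effect gamma_i on the
    exposure (drawn N(0.02, 0.02^2) and sign-fixed positive, BMI-GWAS-like);
    the outcome effect is ``causal_effect * gamma_i`` plus optional direct
    (pleiotropic) effects.  Observed betas add sampling noise at the two
    cohorts' sample sizes.  Columns: beta_exp, se_exp, p_exp, eaf, n_exp,
    beta_out, se_out, n_out.
    """
    rng = np.random.default_rng(seed)
    eaf = rng.uniform(0.05, 0.95, size=k)
    gamma = np.abs(rng.normal(0.02, gamma_sd, size=k)) + 0.005
    var_g = 2 * eaf * (1 - eaf)
    se_exp = 1.0 / np.sqrt(n_exposure * var_g)
    se_out = 1.0 / np.sqrt(n_outcome * var_g)
    beta_exp = gamma + rng.normal(0, se_exp)
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, size=k) if pleiotropy_sd or pleiotropy_mean else 0.0
    beta_out = causal_effect * gamma + alpha + rng.normal(0, se_out)
    p_exp = 2 * stats.norm.sf(np.abs(beta_exp / se_exp))
    return pd.DataFrame(
        {
            "SNP": [f"iv{i:03d}" for i in range(k)],
            "beta_exp": beta_exp,
            "se_exp": se_exp,
            "p_exp": p_exp,
            "eaf": eaf,
            "n_exp": n_exposure,
            "beta_out": beta_out,
            "se_out": se_out,
            "n_out": n_outcome,
        }
    ).set_index("SNP")


def generate_mr_screen_data(
    n_traits: int,
    causal_effects: np.ndarray | float,
    k: int = 30,
    seed: int = 0,
    n_exposure: int = 300_000,
    n_outcome: int = 12_652,
    gamma_sd: float = 0.02,
    obs_noise_sd: float = 0.05,
):
    """Summary data for a many-trait MR screen with one shared exposure.

    Returns ``(bx, by_matrix, sy_matrix, obs_betas, causal_effects)``: one
    instrument set (observed exposure betas ``bx``) and, per trait, observed
    outcome betas/ses plus an observational association beta that equals the
    causal effect contaminated with independent noise (so under the global
    null the observational and MR betas are uncorrelated).
    """
    rng = np.random.default_rng(seed)
    causal = np.broadcast_to(np.asarray(causal_effects, dtype=float), (n_traits,)).copy()
    eaf = rng.uniform(0.05, 0.95, size=k)
    gamma = np.abs(rng.normal(0.02, gamma_sd, size=k)) + 0.005
    var_g = 2 * eaf * (1 - eaf)
    se_exp = 1.0 / np.sqrt(n_exposure * var_g)
    se_out = 1.0 / np.sqrt(n_outcome * var_g)
    bx = gamma + rng.normal(0, se_exp)
    by = causal[:, None] * gamma[None, :] + rng.normal(0, 1, (n_traits, k)) * se_out[None, :]
    sy = np.broadcast_to(se_out, (n_traits, k)).copy()
    obs = causal + rng.normal(0, obs_noise_sd, n_traits)
    return bx, by, sy, obs, causal
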