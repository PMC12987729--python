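"""Species quantification from signature-gene read counts.

The profiler models the read count of each signature gene, conditional on the
total signature-gene count of its species in a sample, as negative binomial
with mean proportional to the gene's effective length and size (dispersion)
parameter log2(effective length).  Genes whose observed count falls outside
the central 99% of that distribution (below the 0.5% or above the 99.5%
quantile) are treated as outliers — e.g. genes shared with an unrepresented
strain, or spuriously recruiting reads — and excluded before averaging.

Rules, applied per species per sample in order:

1. If >=50 signature genes have non-zero counts and, under the model, >=99%
   of genes are expected to be non-zero given the species total, genes with
   zero counts are ignored (their zeros are treated as artefacts).
2. Inclusive 99% quantile bounds are computed per gene and counts outside
   are dropped.
3. Abundance = mean over admitted genes of count / effective length.
4. When <66% of the considered genes have non-zero counts within bounds,
   abundance is zeroed unless the median length-corrected abundance over all
   signature genes is non-zero, in which case the median over non-zero genes
   is used instead of the mean (this fallback can rescue a species whose
   bounds were distorted by contamination).
5. Abundance is zeroed when fewer than five admitted genes are non-zero.
6. Rows are renormalized so each sample's species abundances sum to 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import GeneCatalog

# cell provenance flags stored alongside abundances
FLAG_OK = 0
FLAG_OBSERVED_ZERO = 1     # all signature genes zero / nothing admitted
FLAG_ZEROED_BY_RULE = 2    # <5 non-zero admitted genes or 66% rule zeroed it
FLAG_MEDIAN_FALLBACK = 3   # 66% rule triggered, median of non-zero genes used


# ---------------------------------------------------------------------------
# Read-pair classification
# ---------------------------------------------------------------------------

@dataclass
class Read:
    """One aligned read of a pair; ``gene_id`` is None when unaligned."""

    mapq: int
    identity: float
    aligned_length: int
    unaligned_bases: int
    gene_id: str | None = None


@dataclass
class AlignmentRecord:
    read1: Read
    read2: Read


UNIQUE, MULTI, UNMAPPED = "unique", "multi", "unmapped"


def _read_status(r: Read) -> str:
    aligned_ok = (
        r.identity >= 0.95 and r.aligned_length >= 100 and r.unaligned_bases <= 10
    )
    if not aligned_ok:
        return UNMAPPED
    if r.mapq >= 20 and r.gene_id is not None:
        return UNIQUE
    return MULTI


def classify_read_pairs(records: Sequence[AlignmentRecord]):
    """Classify read pairs as unique / multi / unmapped and count unique genes.

    A read is uniquely mapped when MAPQ >= 20, identity >= 95% over >= 100
    aligned bp, and at most 10 bases fail to align; reads meeting the
    identity/length criteria but not the MAPQ threshold are multi-mapped.  A
    pair is unique if either read is unique (if both are, to different genes,
    read one's gene is counted), multi-mapped if neither is unique but at
    least one is multi-mapped, and unmapped otherwise.

    Returns ``(labels, gene_counts)``.
    """
    labels: list[str] = []
    counts: dict[str, int] = {}
    for rec in records:
        s1, s2 = _read_status(rec.read1), _read_status(rec.read2)
        if s1 == UNIQUE or s2 == UNIQUE:
            labels.append(UNIQUE)
            gene = rec.read1.gene_id if s1 == UNIQUE else rec.read2.gene_id
            counts[gene] = counts.get(gene, 0) + 1
        elif s1 == MULTI or s2 == MULTI:
            labels.append(MULTI)
        else:
            labels.append(UNMAPPED)
    return labels, counts


# ---------------------------------------------------------------------------
# Negative-binomial gene count model
# ---------------------------------------------------------------------------

def nb_size(effective_lengths: np.ndarray) -> np.ndarray:
    """NB size r = log2(effective length), clamped below at 1.

    With size r and mean mu the variance is mu + mu^2 / r; longer genes pool
    more alignment positions and behave closer to Poisson.
    """
    return np.maximum(np.log2(np.maximum(np.asarray(effective_lengths, dtype=float), 2.0)), 1.0)


@dataclass
class QuantileBounds:
    """Per-gene admissible count interval and expected non-zero probability."""

    lower: np.ndarray   # int, inclusive
    upper: np.ndarray   # int, inclusive
    p_nonzero: np.ndarray


def nb_gene_bounds(effective_lengths: np.ndarray, total_count: float) -> QuantileBounds:
    """Expected 99% count quantiles (0.5%..99.5%, inclusive) per signature gene.

    The species' total count is distributed over its genes proportionally to
    effective length: mu_g = total * L_g / sum(L).  total == 0 degenerates to
    all-zero bounds.
    """
    L = np.asarray(effective_lengths, dtype=float)
    if np.any(L < 1):
        raise ValueError("effective lengths must be >= 1")
    if total_count < 0:
        raise ValueError("total count must be >= 0")
    if total_count == 0 or L.sum() == 0:
        z = np.zeros(L.shape, dtype=int)
        return QuantileBounds(z, z.copy(), np.zeros(L.shape))
    mu = total_count * L / L.sum()
    r = nb_size(L)
    p = r / (r + mu)
    lower = stats.nbinom.ppf(0.005, r, p).astype(int)
    upper = stats.nbinom.ppf(0.995, r, p).astype(int)
    p_nonzero = 1.0 - stats.nbinom.pmf(0, r, p)
    return QuantileBounds(lower, upper, p_nonzero)


# ---------------------------------------------------------------------------
# Abundance estimation
# ---------------------------------------------------------------------------

ZERO_IGNORE_MIN_NONZERO = 50
ZERO_IGNORE_EXPECTED_NONZERO = 0.99
MIN_NONZERO_ADMITTED = 5
MIN_NONZERO_FRACTION = 0.66


@dataclass
class SpeciesProfile:
    """Samples x species relative abundances in percent, plus per-cell flags.

    Non-empty rows sum to 100 (within 1e-6); rows of samples with no
    quantifiable species sum to 0.  ``flags`` records, per cell, whether the
    value was observed, zeroed by a filtering rule, or produced by the
    median fallback.
    """

    abundance: pd.DataFrame
    flags: pd.DataFrame

    def prevalence(self) -> pd.Series:
        return (self.abundance > 0).mean(axis=0)

    def filter_prevalence(self, min_prevalence: float = 0.30) -> "SpeciesProfile":
        keep = self.prevalence() >= min_prevalence
        return SpeciesProfile(self.abundance.loc[:, keep], self.flags.loc[:, keep])

    def to_tsv(self, path) -> None:
        self.abundance.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path) -> "SpeciesProfile":
        ab = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(ab, pd.DataFrame(FLAG_OK, index=ab.index, columns=ab.columns))

    def to_triplets(self, path) -> None:
        """Sparse triplet TSV (sample, species, abundance), BIOM-style."""
        stacked = self.abundance.stack()
        stacked = stacked[stacked > 0]
        stacked.rename_axis(["sample_id", "species_id"]).rename("abundance").reset_index().to_csv(
            path, sep="\t", index=False
        )


def _species_abundance_one_sample(counts: np.ndarray, eff_len: np.ndarray):
    """Apply the filtering rules for one species in one sample.

    Returns (abundance on the per-gene count/length scale, flag).
    """
    total = counts.sum()
    if total == 0:
        return 0.0, FLAG_OBSERVED_ZERO

    considered = np.ones(counts.shape, dtype=bool)
    n_nonzero = int((counts > 0).sum())
    if n_nonzero >= ZERO_IGNORE_MIN_NONZERO:
        full_bounds = nb_gene_bounds(eff_len, total)
        if full_bounds.p_nonzero.mean() >= ZERO_IGNORE_EXPECTED_NONZERO:
            considered = counts > 0

    c = counts[considered]
    L = eff_len[considered]
    bounds = nb_gene_bounds(L, c.sum())
    admitted = (c >= bounds.lower) & (c <= bounds.upper)

    nonzero_admitted = admitted & (c > 0)
    # the 66% rule is checked first: its median fallback can rescue a species
    # whose bounds were distorted (e.g. by contamination inflating the total)
    if nonzero_admitted.sum() / considered.sum() < MIN_NONZERO_FRACTION:
        per_gene = counts / eff_len
        if np.median(per_gene) > 0:
            nz = per_gene[counts > 0]
            return float(np.median(nz)), FLAG_MEDIAN_FALLBACK
        return 0.0, FLAG_ZEROED_BY_RULE

    if nonzero_admitted.sum() < MIN_NONZERO_ADMITTED:
        return 0.0, FLAG_ZEROED_BY_RULE

    return float(np.mean(c[admitted] / L[admitted])), FLAG_OK


def estimate_abundances(counts: pd.DataFrame, catalog: GeneCatalog) -> SpeciesProfile:
    """Estimate species relative abundances (percent) from a gene count table.

    ``counts`` is samples x genes (unique read-pair counts); only signature
    genes present in the catalog are used.  See the module docstring for the
    filtering rules.
    """
    sig = catalog.signature_genes()
    species_ids = catalog.species_ids
    samples = counts.index
    raw_np = np.zeros((len(samples), len(species_ids)))
    flags_np = np.full((len(samples), len(species_ids)), FLAG_OBSERVED_ZERO, dtype=int)

    for j, sp in enumerate(species_ids):
        genes = sig[sig["species_id"] == sp]
        gene_ids = [g for g in genes["gene_id"] if g in counts.columns]
        if not gene_ids:
            continue  # species without signature genes: abundance 0
        eff_len = genes.set_index("gene_id").loc[gene_ids, "effective_length"].to_numpy(dtype=float)
        sub = counts[gene_ids].to_numpy()
        for i in range(len(samples)):
            raw_np[i, j], flags_np[i, j] = _species_abundance_one_sample(sub[i], eff_len)

    raw = pd.DataFrame(raw_np, index=samples, columns=species_ids)
    flags = pd.DataFrame(flags_np, index=samples, columns=species_ids)
    row_sums = raw.sum(axis=1)
    nonzero = row_sums > 0
    raw.loc[nonzero] = raw.loc[nonzero].div(row_sums[nonzero], axis=0) * 100.0
    return SpeciesProfile(raw, flags)


# ---------------------------------------------------------------------------
# Rarefaction and alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class RarefiedProfile:
    profile: SpeciesProfile
    rarefied_counts: pd.DataFrame
    excluded_samples: list
    target: int


def rarefy_counts(counts: pd.DataFrame, catalog: GeneCatalog, target: int, seed: int) -> RarefiedProfile:
    """Subsample ``target`` signature-gene read pairs per sample without replacement.

    Samples with fewer than ``target`` total signature counts are excluded
    (flagged, not an error).  The rarefied table is then re-profiled with
    :func:`estimate_abundances`.
    """
    if target < 1:
        raise ValueError("rarefaction target must be >= 1")
    rng = np.random.default_rng(seed)
    sig_ids = [g for g in catalog.signature_genes()["gene_id"] if g in counts.columns]
    sig_counts = counts[sig_ids]
    totals = sig_counts.sum(axis=1)
    keep = totals >= target
    excluded = list(counts.index[~keep])

    rows = []
    for _, row in sig_counts[keep].iterrows():
        vec = row.to_numpy(dtype=np.int64)
        if vec.sum() == target:
            rows.append(vec)
        else:
            rows.append(rng.multivariate_hypergeometric(vec, target, method="marginals"))
    rare = pd.DataFrame(rows, index=sig_counts.index[keep], columns=sig_ids, dtype=np.int64)
    profile = estimate_abundances(rare, catalog)
    return RarefiedProfile(profile, rare, excluded, target)


def rarefy_profile(counts: pd.DataFrame, catalog: GeneCatalog, target: int, seed: int) -> SpeciesProfile:
    return rarefy_counts(counts, catalog, target, seed).profile


def alpha_diversity(profile: SpeciesProfile) -> pd.DataFrame:
    """Shannon index (natural log) and richness per sample.

    shannon = -sum p_i ln p_i over species with non-zero relative abundance
    (p_i = abundance / 100); richness = number of such species.  Empty rows
    yield shannon 0, richness 0.
    """
    ab = profile.abundance.to_numpy(dtype=float) / 100.0
    shannon = np.zeros(ab.shape[0])
    richness = np.zeros(ab.shape[0], dtype=int)
    for i, row in enumerate(ab):
        p = row[row > 0]
        richness[i] = p.size
        if p.size:
            p = p / p.sum()
            shannon[i] = float(-(p * np.log(p)).sum())
    return pd.DataFrame({"shannon": shannon, "richness": richness}, index=profile.abundance.index)


# ---------------------------------------------------------------------------
# KO functional profiles
# ---------------------------------------------------------------------------

def ko_profile(counts: pd.DataFrame, catalog: GeneCatalog) -> pd.DataFrame:
    """KO functional potential: proportion of total gene abundance per KO.

    Gene abundance is count / effective length (all catalog genes, not just
    signature genes); each KO's value is the summed abundance of genes
    annotated to it divided by the summed abundance of all genes, so values
    lie in [0, 1] and per-sample KO sums are <= 1 (unannotated abundance is
    counted in the denominator only).  All-zero samples yield all-zero rows.
    """
    genes = catalog.genes.set_index("gene_id")
    gene_ids = [g for g in counts.columns if g in genes.index]
    eff = genes.loc[gene_ids, "effective_length"].to_numpy(dtype=float)
    kos = genes.loc[gene_ids, "ko"].fillna("").to_numpy()

    abund = counts[gene_ids].to_numpy(dtype=float) / eff
    total = abund.sum(axis=1)
    ko_labels = sorted({k for k in kos if k})
    out = np.zeros((counts.shape[0], len(ko_labels)))
    for j, ko in enumerate(ko_labels):
        out[:, j] = abund[:, kos == ko].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total[:, None] > 0, out / total[:, None], 0.0)
    return pd.DataFrame(out, index=counts.index, columns=ko_labels)
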