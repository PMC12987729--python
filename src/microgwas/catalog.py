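"""Gene catalog, signature-gene selection and KEGG module machinery.

A metagenomic *gene catalog* assigns every gene to a species pangenome and
annotates it with a length and (optionally) a KEGG Orthology (KO) label.
Species are quantified from *signature genes*: species-unique core genes used
as abundance markers.  KEGG *modules* are sets of KOs, possibly organised in
alternative reaction paths of ordered steps; a species is associated with a
module when it carries enough of the module's KOs to plausibly complete the
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Alignment criterion (bp) used when converting gene length to an effective
#: length for count normalization: a read must align over at least this many
#: bases, so the number of distinct valid start positions on a gene of length
#: L is roughly L - MIN_ALIGN_LEN + 1.
MIN_ALIGN_LEN = 100

SIGNATURE_GENE_CAP = 250
SIGNATURE_MIN_LENGTH = 200
SIGNATURE_MAX_LENGTH = 20_000
CORE_GENE_PREVALENCE = 0.60


def effective_length(length: np.ndarray | int, min_align_len: int = MIN_ALIGN_LEN):
    """Effective gene length: number of valid alignment start positions.

    ``max(L - min_align_len + 1, 1)``; lengths shorter than the alignment
    criterion still get a floor of 1 so normalization never divides by zero.
    """
    return np.maximum(np.asarray(length) - min_align_len + 1, 1)


class GeneCatalog:
    """Container for a gene catalog.

    Wraps a DataFrame with columns ``gene_id, species_id, length,
    effective_length, is_signature, ko`` (ko may be empty string for
    unannotated genes).
    """

    REQUIRED = ("gene_id", "species_id", "length", "effective_length", "is_signature", "ko")

    def __init__(self, genes: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in genes.columns]
        if missing:
            raise ValueError(f"gene catalog missing columns: {missing}")
        self.genes = genes.reset_index(drop=True)

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.genes["species_id"].unique())

    def signature_genes(self, species_id: str | None = None) -> pd.DataFrame:
        sig = self.genes[self.genes["is_signature"]]
        if species_id is not None:
            sig = sig[sig["species_id"] == species_id]
        return sig

    def to_tsv(self, path: str | Path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneCatalog":
        genes = pd.read_csv(path, sep="\t", dtype={"ko": str}, keep_default_na=False)
        genes["is_signature"] = genes["is_signature"].astype(bool)
        return cls(genes)


# ---------------------------------------------------------------------------
# Signature-gene selection from pangenomes
# ---------------------------------------------------------------------------

@dataclass
class Pangenome:
    """A species pangenome: genes with MAG presence vectors and uniqueness flags.

    ``presence`` is a genes x MAGs boolean matrix; ``is_unique`` marks genes
    with no shared >=100 bp segment at >97% identity with any other catalog
    gene (precomputed upstream; sequence scanning is out of scope here).
    """

    species_id: str
    gene_ids: Sequence[str]
    lengths: np.ndarray
    presence: np.ndarray  # genes x MAGs, bool
    is_unique: np.ndarray  # genes, bool

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths)
        self.presence = np.asarray(self.presence, dtype=bool)
        self.is_unique = np.asarray(self.is_unique, dtype=bool)
        n = len(self.gene_ids)
        if not (len(self.lengths) == self.presence.shape[0] == len(self.is_unique) == n):
            raise ValueError("pangenome fields have inconsistent gene counts")

    @property
    def prevalence(self) -> np.ndarray:
        return self.presence.mean(axis=1)


@dataclass
class SignatureSelection:
    species_id: str
    gene_ids: list[str]
    fallback_needed: bool


def select_signature_genes(pangenome: Pangenome, cap: int = SIGNATURE_GENE_CAP) -> SignatureSelection:
    """Select up to ``cap`` signature genes for a species.

    Eligibility: core gene (prevalence >= 60% across the species' MAGs),
    length within [200, 20000] bp, and species-unique.  When more than ``cap``
    genes are eligible the deterministic priority is higher prevalence, then
    longer gene, then lexicographic gene id.  Species with fewer than 20
    eligible genes are flagged ``fallback_needed`` (the segment-masking
    fallback is not implemented).
    """
    if len(pangenome.gene_ids) == 0:
        raise ValueError("empty pangenome")
    prev = pangenome.prevalence
    eligible = (
        (prev >= CORE_GENE_PREVALENCE)
        & (pangenome.lengths >= SIGNATURE_MIN_LENGTH)
        & (pangenome.lengths <= SIGNATURE_MAX_LENGTH)
        & pangenome.is_unique
    )
    idx = np.flatnonzero(eligible)
    order = sorted(idx, key=lambda i: (-prev[i], -pangenome.lengths[i], pangenome.gene_ids[i]))
    chosen = [pangenome.gene_ids[i] for i in order[:cap]]
    return SignatureSelection(pangenome.species_id, chosen, fallback_needed=len(idx) < 20)


# ---------------------------------------------------------------------------
# KEGG modules
# ---------------------------------------------------------------------------

@dataclass
class KeggModuleDef:
    """A KEGG module: alternative reaction paths, each an ordered list of steps.

    Each step is a set of KOs (alternative orthologs catalysing that step).
    """

    module_id: str
    paths: list[list[frozenset[str]]]
    name: str = ""

    def __post_init__(self):
        if not self.paths:
            raise ValueError(f"module {self.module_id}: needs at least one path")
        for path in self.paths:
            if not path or any(len(step) == 0 for step in path):
                raise ValueError(f"module {self.module_id}: empty step or path")
        self.paths = [[frozenset(step) for step in path] for path in self.paths]

    def all_kos(self) -> frozenset[str]:
        return frozenset().union(*(ko for path in self.paths for ko in path))


@dataclass
class AssociationRecord:
    module_id: str
    associated: bool
    completeness: float          # best path's fraction of KOs present
    path_index: int              # which path achieved it
    small_module_rule_applied: bool


COMPLETENESS_THRESHOLD = 2.0 / 3.0


def species_module_association(species_kos: Iterable[str], module: KeggModuleDef) -> AssociationRecord:
    """Decide whether a species is associated with a KEGG module.

    Association requires some path whose distinct KOs are >= 2/3 present in
    the species; for paths of three or fewer steps every step must in
    addition have at least one KO present (short modules tolerate no gaps).
    Completeness is KO-weighted over the distinct KOs of the path.
    """
    kos = frozenset(species_kos)
    best = (-1.0, -1, False, False)  # completeness, path idx, small rule, associated
    for p_idx, path in enumerate(module.paths):
        path_kos = frozenset().union(*path)
        frac = len(kos & path_kos) / len(path_kos)
        small = len(path) <= 3
        ok = frac >= COMPLETENESS_THRESHOLD - 1e-12
        if small:
            ok = ok and all(kos & step for step in path)
        # prefer an associating path; among ties, higher completeness
        key = (1 if ok else 0, frac)
        best_key = (1 if best[3] else 0, best[0])
        if key > best_key:
            best = (frac, p_idx, small, ok)
    frac, p_idx, small, ok = best
    return AssociationRecord(module.module_id, ok, frac, p_idx, small)


def build_module_association(
    species_kos: Mapping[str, Iterable[str]], modules: Sequence[KeggModuleDef]
) -> "ModuleAssociation":
    records = {
        sp: {m.module_id: species_module_association(kos, m) for m in modules}
        for sp, kos in species_kos.items()
    }
    matrix = pd.DataFrame(
        {m.module_id: [records[sp][m.module_id].associated for sp in species_kos] for m in modules},
        index=list(species_kos),
    )
    return ModuleAssociation(matrix, records)


@dataclass
class ModuleAssociation:
    """Species x module boolean matrix with per-cell audit records."""

    matrix: pd.DataFrame  # species x modules, bool
    records: dict[str, dict[str, AssociationRecord]] = field(default_factory=dict)


def module_abundance_profile(profile: pd.DataFrame, assoc: ModuleAssociation) -> pd.DataFrame:
    """Module relative-abundance profile: sum of associated species' abundances.

    ``profile`` is samples x species in percent (rows sum to 100); the result
    is samples x modules, each value the summed relative abundance of the
    species associated with that module, hence in [0, 100].
    """
    common = [sp for sp in profile.columns if sp in assoc.matrix.index]
    mat = assoc.matrix.loc[common].astype(float)
    return profile[common] @ mat


# ---------------------------------------------------------------------------
# Module-definition TSV round trip (module id, path index, step index, KO list)
# ---------------------------------------------------------------------------

def write_module_defs(modules: Sequence[KeggModuleDef], path: str | Path) -> None:
    rows = []
    for m in modules:
        for p_idx, p in enumerate(m.paths):
            for s_idx, step in enumerate(p):
                rows.append(
                    {
                        "module_id": m.module_id,
                        "path_index": p_idx,
                        "step_index": s_idx,
                        "kos": ",".join(sorted(step)),
                        "name": m.name,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_module_defs(path: str | Path) -> list[KeggModuleDef]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    modules = []
    for mid, sub in df.groupby("module_id", sort=True):
        paths = []
        for _, psub in sub.groupby("path_index", sort=True):
            psub = psub.sort_values("step_index", key=lambda s: s.astype(int))
            paths.append([frozenset(k.split(",")) for k in psub["kos"]])
        name = sub["name"].iloc[0] if "name" in sub else ""
        modules.append(KeggModuleDef(mid, paths, name=name))
    return modules
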