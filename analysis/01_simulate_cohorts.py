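#!/usr/bin/env python
"""Simulate the study's inputs: a gene catalog with signature genes and KEGG
modules, a discovery cohort and a replication cohort with shared planted
SNP -> species effects, and the discovery cohort's read-count table.

Writes everything downstream steps consume under results/sim/.
"""

from pathlib import Path

from microgwas import io
from microgwas.catalog import write_module_defs
from microgwas.synthetic_data import (
    DiseaseModel,
    SimConfig,
    SnpEffect,
    generate_catalog,
    generate_cohort_pair,
    generate_counts,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

# planted per-allele effects mirror the magnitudes of replicated
# host-genotype -> gut-species signals (|beta| 0.05-0.19 s.d. per allele)
CONFIG = SimConfig(
    seed=101,
    n_samples=2500,
    n_species=30,
    genes_per_species=300,
    depth=1_300_000.0,
    n_snps=60,
    ld_block_size=3,
    maf_range=(0.1, 0.5),
    effect_table=[
        SnpEffect("rs00009", "sp004", -0.14),   # LCT-like negative signal
        SnpEffect("rs00027", "sp011", 0.11),    # ABO-like positive signal
        SnpEffect("rs00045", "sp020", 0.19),    # rarer, stronger signal
    ],
    bmi_effects={"sp002": -0.10, "sp007": 0.08, "sp013": -0.06},
    disease_model=DiseaseModel("sp004", -3.5, -0.6),
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    catalog, modules = generate_catalog(CONFIG)
    disc, repl = generate_cohort_pair(CONFIG, replication_n=3200)

    counts = generate_counts(catalog, disc.truth, disc.config)
    catalog.to_tsv(OUT / "catalog.tsv")
    write_module_defs(modules, OUT / "modules.tsv")
    io.write_counts(counts.iloc[:120], OUT / "discovery_counts_subset.tsv")

    for name, cohort in [("discovery", disc), ("replication", repl)]:
        io.write_genotypes_tsv(cohort.genotypes.dosages, OUT / f"{name}_genotypes.tsv")
        cohort.traits.to_csv(OUT / f"{name}_traits.tsv", sep="\t", index_label="sample_id")
        cohort.truth.true_compositions.to_csv(OUT / f"{name}_truth_compositions.tsv",
                                              sep="\t", index_label="sample_id")
    io.write_vcf(disc.genotypes.dosages.iloc[:50], disc.genotypes.variants,
                 OUT / "discovery_genotypes_head.vcf")

    print(f"catalog: {len(catalog.genes)} genes, "
          f"{int(catalog.genes.is_signature.sum())} signature, "
          f"{len(modules)} KEGG modules")
    print(f"discovery n={CONFIG.n_samples}, replication n=3200, "
          f"{CONFIG.n_snps} SNPs, {len(CONFIG.effect_table)} planted SNP effects")
    print(f"count table written for 120 discovery samples "
          f"({counts.iloc[:120].to_numpy().sum():,} read pairs)")
    print(f"outputs in {OUT}")


if __name__ == "__main__":
    main()
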