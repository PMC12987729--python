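import numpy as np
import pandas as pd
import pytest

from microgwas.catalog import GeneCatalog
from microgwas.synthetic_data import (
    SimConfig,
    generate_catalog,
    generate_counts,
    generate_truth,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small but fully featured community: 20 species, 250 signature genes."""
    return SimConfig(seed=11, n_samples=20, n_species=20, genes_per_species=300,
                     depth=1_300_000.0)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    """(catalog, modules, truth, counts) for the small community."""
    catalog, modules = generate_catalog(small_cfg)
    truth = generate_truth(small_cfg)
    counts = generate_counts(catalog, truth, small_cfg)
    return catalog, modules, truth, counts


def toy_catalog(n_genes: int, eff_len: float, species_id: str = "spX",
                kos=None) -> GeneCatalog:
    """Single-species catalog with equal-effective-length signature genes."""
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "species_id": species_id,
            "length": int(eff_len) + 99,
            "effective_length": eff_len,
            "is_signature": True,
            "ko": kos if kos is not None else "",
        }
    )
    return GeneCatalog(genes)
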