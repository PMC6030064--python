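import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from chromfate.core_io import FragmentSet, GenomicInterval, TssAnnotation
from chromfate.synthetic_data import SimulationConfig

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A scaled-down study: fast enough for unit tests, same structure."""
    return SimulationConfig(
        seed=11,
        chromosomes={"chr1": 3_000_000, "chr2": 3_000_000},
        n_genes=120,
        background_fragments=40_000,
        region_chromosomes={"chrU": 2_000_000},
        n_enriched_regions=2,
        n_shared_peaks=10,
        fate_counts={
            "loss": 8,
            "Sox2_replacement": 6,
            "Nanog_replacement": 4,
            "Sox2_Nanog_replacement": 2,
        },
        n_atac_peaks=60,
        atac_background_fragments=60_000,
        genes_per_module=30,
        n_constant_genes=10,
        n_decoy_proteins=15,
        n_planted_interactors=4,
        n_background_proteins=3,
    )


@pytest.fixture
def tiny_tss() -> TssAnnotation:
    return TssAnnotation(
        pd.DataFrame(
            {
                "gene_id": ["geneA", "geneB", "geneC"],
                "chrom": ["chr1", "chr1", "chr2"],
                "strand": ["+", "-", "+"],
                "tss": [10_000, 40_000, 5_000],
            }
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_fragments(library_id, triples):
    return FragmentSet.from_intervals(
        library_id, [GenomicInterval(c, s, e) for c, s, e in triples]
    )


@pytest.fixture
def make_fragset():
    return make_fragments
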