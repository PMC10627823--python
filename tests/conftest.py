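import numpy as np
import pandas as pd
import pytest

from orthoexpress import (
    CellPopulationDataset,
    OrthologyMap,
    PseudobulkProfile,
    SimulationConfig,
    pseudobulk,
    simulate_dataset,
    taxonomy_from_truth,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_species=3,
        n_cell_types=9,
        cells_per_type=40,
        n_genes=300,
        coexpr_module_count=3,
        module_size=12,
        divergent_gene_ids=("g00000", "g00013"),
        seed=1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """Three-species synthetic cohort with two planted divergent genes."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_profiles(small_sim):
    datasets, _, truth = small_sim
    taxonomy = taxonomy_from_truth(truth)
    return {ds.species: pseudobulk(ds, taxonomy) for ds in datasets}


def make_profile(matrix: np.ndarray, species: str, genes=None, cell_types=None) -> PseudobulkProfile:
    matrix = np.asarray(matrix, dtype=float)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    cell_types = cell_types or [f"ct{j}" for j in range(matrix.shape[1])]
    return PseudobulkProfile(pd.DataFrame(matrix, index=genes, columns=cell_types), species)


def make_dataset(counts: np.ndarray, species: str, clusters, genes=None) -> CellPopulationDataset:
    counts = np.asarray(counts)
    genes = genes or [f"g{i}" for i in range(counts.shape[0])]
    meta = pd.DataFrame(
        {
            "species": species,
            "donor": "d0",
            "cluster": list(clusters),
            "class_label": "c",
            "subclass": "s",
        }
    )
    return CellPopulationDataset(counts, pd.Index(genes), meta, species)


def identity_orthology(species, genes) -> OrthologyMap:
    return OrthologyMap.identity(species, list(genes))
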