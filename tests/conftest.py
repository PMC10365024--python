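import numpy as np
import pytest

from porcupine import (
    CovariateSpec,
    EdgeMatrix,
    PathwayCollection,
    PlantedSpec,
    SimulationSpec,
    simulate_cohort,
)


@pytest.fixture
def tiny_matrix() -> EdgeMatrix:
    """3 TFs x 4 genes x 5 samples, full bipartite, reproducible weights."""
    rng = np.random.default_rng(42)
    tf_names = ["TFa", "TFb", "TFc"]
    gene_names = ["g1", "g2", "g3", "g4"]
    tfs = [tf for g in gene_names for tf in tf_names]
    genes = [g for g in gene_names for _ in tf_names]
    samples = [f"s{i}" for i in range(5)]
    weights = rng.normal(size=(len(tfs), len(samples)))
    return EdgeMatrix(tfs=tfs, genes=genes, samples=samples, weights=weights)


@pytest.fixture
def tiny_collection() -> PathwayCollection:
    return PathwayCollection(
        {
            "P_first": {"g1", "g2", "g3"},
            "P_second": {"g3", "g4"},
            "P_outside": {"g2", "g4", "gX"},
        }
    )


@pytest.fixture(scope="session")
def null_cohort():
    """Small null cohort (no planted structure) shared across tests."""
    spec = SimulationSpec(
        n_tfs=10, n_genes=120, n_samples=30, n_pathways=8,
        pathway_size_range=(8, 20), seed=7,
    )
    matrix, collection, _, truth = simulate_cohort(spec)
    return matrix, collection, truth


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a strong planted latent factor in one pathway."""
    spec = SimulationSpec(
        n_tfs=10, n_genes=120, n_samples=30, n_pathways=8,
        pathway_size_range=(8, 20),
        planted=PlantedSpec(pathway_index=2, factor_strength=2.0),
        covariates=CovariateSpec(n_levels=3, numerical_link=0.8),
        seed=11,
    )
    return simulate_cohort(spec)
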