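import numpy as np
import pytest

from coexmod import (
    SimulationConfig,
    simulate_collection,
    normalize_tissue,
    pearson_profile,
    rsum_ranking,
    NormalizedMatrix,
)

# Small but structurally faithful panel: the full 20 tissues, a planted
# module, but a reduced gene universe and donor count so fixtures build in
# about a second.
SMALL_CFG = SimulationConfig(
    n_tissues=20,
    n_samples_per_tissue=25,
    n_genes=120,
    module_size=12,
    effect_size=1.0,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_collection():
    matrices, truth = simulate_collection(SMALL_CFG)
    return SMALL_CFG, matrices, truth


@pytest.fixture(scope="session")
def small_ranking(small_collection):
    cfg, matrices, truth = small_collection
    profiles = [
        pearson_profile(normalize_tissue(tm), truth.seed_gene_id) for tm in matrices
    ]
    return rsum_ranking(profiles)


@pytest.fixture()
def toy_norm():
    """A 10-gene x 8-sample normalized matrix with known structure."""
    rng = np.random.default_rng(123)
    values = rng.normal(size=(10, 8))
    gene_ids = [f"g{i}" for i in range(10)]
    values[1] = values[0]                       # exact copy of g0
    values[2] = -2.0 * values[0] + 5.0          # affine anti-correlate of g0
    values[3] = 1.5                             # zero variance
    return NormalizedMatrix(
        gene_ids=gene_ids,
        sample_ids=[f"s{j}" for j in range(8)],
        values=values,
        factors=np.ones(8),
        tissue_name="toy",
    )
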