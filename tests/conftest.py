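import numpy as np
import pandas as pd
import pytest

from coexscreen import (
    ExpressionAtlas,
    ModuleSpec,
    SyntheticAtlasConfig,
    compute_similarity,
    preprocess_atlas,
    simulate_atlas,
)


@pytest.fixture
def random_atlas_factory():
    """Small random TPM atlases for oracle comparisons."""

    def make(n_genes: int, n_samples: int, seed: int) -> ExpressionAtlas:
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3.0, 1.0, size=(n_genes, n_samples))
        df = pd.DataFrame(
            values,
            index=[f"g{i:02d}" for i in range(n_genes)],
            columns=[f"s{i:02d}" for i in range(n_samples)],
        )
        return ExpressionAtlas(values=df)

    return make


@pytest.fixture
def two_module_config():
    """Zero-noise atlas: two orthogonal block modules, no background."""
    return SyntheticAtlasConfig(
        modules=[
            ModuleSpec("M1", 4, 2, [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
            ModuleSpec("M2", 4, 2, [0.0, 0.0, 0.0, 1.0, 2.0, 1.0]),
        ],
        n_samples=6,
        background_gene_count=0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def planted_setup():
    """Study-scale atlas (82 samples, 3 modules, 5 regulators each, low noise)
    with its ranking, for recovery tests."""
    from coexscreen import default_atlas_config

    config = default_atlas_config(seed=1, noise_sd=0.05)
    atlas, truth = simulate_atlas(config)
    ranking = compute_similarity(preprocess_atlas(atlas))
    return atlas, truth, ranking
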