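import numpy as np
import pytest

import spnatlas as sa


@pytest.fixture(scope="session")
def small_atlas():
    """Quick synthetic atlas: 5 planted types, no second-order population."""
    cfg = sa.AtlasSimConfig(
        n_types=5, nuclei_per_type=60, n_genes=500, n_marker_genes_per_type=10,
        marker_logfc=1.5, frac_second_order_types=0.0, seed=11,
    )
    return sa.generate_count_matrix(cfg)


@pytest.fixture(scope="session")
def default_atlas():
    """The default study conditions: 12 types x 300 nuclei x 2000 genes."""
    return sa.generate_count_matrix(sa.AtlasSimConfig(seed=7))


@pytest.fixture(scope="session")
def default_atlas_pipeline(default_atlas):
    """Full normalize/PCA/cluster/UMAP run on the default atlas (computed once)."""
    ad, emb, clustering = sa.standard_pipeline(
        default_atlas, seed=0, compute_umap=True
    )
    return ad, emb, clustering


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
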