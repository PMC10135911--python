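import numpy as np
import pytest

import momentgrn as mg


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated study: 60 genes, 5 TFs × 4 targets, 120 samples."""
    cfg = mg.SimulationConfig(
        n_genes=60, n_tfs=5, targets_per_tf=4, n_samples=120, seed=11
    )
    gold = mg.simulate_network(cfg)
    matrix = mg.simulate_expression(gold, cfg)
    return cfg, gold, matrix


@pytest.fixture(scope="session")
def feature_table(small_sim):
    """Standardized + PCA-reduced moment table for the small study."""
    _, gold, matrix = small_sim
    z, _ = mg.zscore_genes(mg.log_transform(matrix))
    pairs = mg.enumerate_pairs(z.gene_ids)
    table = mg.compute_moments(z, pairs)
    table, _, _ = mg.standardize_moments(table)
    pca = mg.fit_pca(table, n_components=36)
    return mg.transform_pca(pca, table), gold


@pytest.fixture()
def blobs():
    """Two well-separated Gaussian blobs, 10 points each (seeded)."""
    rng = np.random.default_rng(42)
    X = np.vstack(
        [
            rng.normal(loc=-3.0, scale=0.3, size=(10, 2)),
            rng.normal(loc=3.0, scale=0.3, size=(10, 2)),
        ]
    )
    y = np.concatenate([np.zeros(10, int), np.ones(10, int)])
    return X, y
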