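import numpy as np
import pytest

import phyloexpress as px


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-species dataset small enough for every stage to run in seconds."""
    cfg = px.SimulationConfig(
        n_species=5,
        n_orthogroups=150,
        samples_per_species_per_treatment=4,
        seed=11,
    )
    return px.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def og_de_tables(small_dataset):
    ds = small_dataset
    return px.run_species_de(ds.counts, ds.metadata, ds.og_map, level="orthogroup")


@pytest.fixture(scope="session")
def tx_de_tables(small_dataset):
    ds = small_dataset
    return px.run_species_de(ds.counts, ds.metadata, level="transcript")


@pytest.fixture(scope="session")
def tree14():
    return px.simulate_tree(14, seed=7)


@pytest.fixture(scope="session")
def corr14(tree14):
    from phyloexpress.phylo_signal import _as_corr

    return _as_corr(px.tree_to_covariance(tree14), None)


@pytest.fixture(scope="session")
def chol14(corr14):
    return np.linalg.cholesky(corr14 + 1e-10 * np.eye(len(corr14)))
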