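import pytest

from gexmol import TranscriptomeMoleculeModel, load_molecule_pool, make_dataset


@pytest.fixture(scope="session")
def pool():
    return load_molecule_pool()


@pytest.fixture(scope="session")
def small_ds():
    """20 noiseless planted samples over 24 genes (fast everywhere)."""
    return make_dataset(20, n_cell_lines=4, gene_count=24, noise_sd=0.0,
                        effect_size=5.0, seed=1)


@pytest.fixture(scope="session")
def tiny_results(small_ds):
    """A briefly trained width-16 model shared by tests that need any
    fitted checkpoint (not a well-trained one)."""
    model = TranscriptomeMoleculeModel(small_ds, d=16, n_layers=1, n_heads=2,
                                       d_ff=32, dropout=0.0)
    return model.fit(epochs=25, lr=1e-3, seed=0)
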