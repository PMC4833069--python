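import pytest

from plastidkit import pipeline, simulate, variants


@pytest.fixture(scope="session")
def toy8_dataset():
    """One fully simulated toy8 dataset (20 kb, 8 taxa, seed 7)."""
    cfg = pipeline.toy8_config(seed=7)
    return cfg, simulate.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def toy8_matrix(toy8_dataset):
    cfg, ds = toy8_dataset
    return variants.build_variant_matrix(ds.pileups, ds.reference, ds.mask)
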