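"""Shared fixtures: the packaged reference panel and small synthetic sets."""

import numpy as np
import pytest

import retorder as ro


@pytest.fixture(scope="session")
def panel():
    return ro.load_reference_panel()


@pytest.fixture(scope="session")
def tiny_noise_free():
    """Small noise-free library: RT is an exact linear function of structure."""
    cfg = ro.GeneratorConfig(n_molecules=40, seed=7, noise_sd=0.0)
    return cfg, ro.synthetic_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_workflow(tiny_noise_free):
    """Trained workflow on the tiny noise-free library (no reference panel)."""
    _, records = tiny_noise_free
    return ro.run_order_workflow(records, n_subsets=4, k_components=25)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
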