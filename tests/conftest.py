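import numpy as np
import pytest

from picmix.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def synth_result():
    """Small synthetic dataset shared across tests (deterministic)."""
    cfg = SynthConfig(n_cells=150, n_peaks=60, n_genes=20, seed=11)
    return generate(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
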