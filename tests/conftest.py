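import numpy as np
import pandas as pd
import pytest

from landsea import synth


@pytest.fixture(scope="session")
def small_bundle():
    """One small seeded synthetic coastline shared by read-only tests."""
    cfg = synth.SynthConfig(n_cells=250, n_reefs=30, rng_seed=11)
    return synth.generate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
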