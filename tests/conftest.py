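import numpy as np
import pytest

from surfppi.synthetic import SynthConfig, gen_proteins


@pytest.fixture(scope="session")
def small_proteins():
    """A small deterministic protein set shared by read-only tests."""
    return gen_proteins(SynthConfig(seed=11, n_proteins=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
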