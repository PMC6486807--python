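import numpy as np
import pytest

from plastevo.simulate import fixture_figure5


@pytest.fixture(scope="session")
def fig5():
    """The three reference architectures at 1/10 linear scale (big pair
    ~1.3 kb, genomes ~12 kb) — large enough for the 1-kb DR/IR threshold,
    small enough for fast tests."""
    return fixture_figure5(scale=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
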