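import numpy as np
import pytest

from bsadesign import DesignPoint


@pytest.fixture
def h_design():
    """Yeast-like haploid design: a minor QTL in a mid-size population."""
    return DesignPoint.make("H", h2=0.03, n=1500, p=0.25, gamma=1.0, u=3.93)


@pytest.fixture
def f2_design():
    """Rice-like F2 design used throughout the precision examples."""
    return DesignPoint.make("F2", h2=0.05, n=1000, p=0.25, gamma=1.0, u=3.65)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
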