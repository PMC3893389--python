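import numpy as np
import pytest

from distmap.synthetic import FoldSpec, make_fold


@pytest.fixture(scope="session")
def mixed_fold():
    """A 30-residue mixed alpha/beta fold with its secondary structure."""
    spec = FoldSpec((("C", 3), ("H", 8), ("C", 3), ("E", 4), ("C", 4),
                     ("H", 6), ("C", 2)), seed=1)
    return make_fold(spec)


@pytest.fixture(scope="session")
def coil_fold():
    """An all-coil fold: every bond is exactly 3.803 A, no strands."""
    return make_fold(FoldSpec((("C", 25),), seed=3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
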