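import numpy as np
import pytest

from mtweezers import BeadModel, MagnetAssembly, TetherModel, WlcParams


@pytest.fixture(scope="session")
def assembly():
    return MagnetAssembly()


@pytest.fixture(scope="session")
def bead():
    return BeadModel()


@pytest.fixture(scope="session")
def wlc_7kb():
    """7.3 kb dsDNA at 0.34 nm/bp."""
    return WlcParams(2.482, 50.0)


@pytest.fixture(scope="session")
def tether_7kb(wlc_7kb):
    return TetherModel(wlc=wlc_7kb, f0_pn=6.4)


@pytest.fixture(scope="session")
def gradient_force_table(assembly, bead):
    """On-axis force vs magnet height under the ∇(m·B) convention (1–8 mm)."""
    from mtweezers import force_vs_height

    return force_vs_height(assembly, bead, (1.0, 8.0), 60, convention="gradient")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
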