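import numpy as np
import pytest

import zsrelax as zr


@pytest.fixture
def single_site():
    """One uncoupled proton at 1 ppm."""
    return zr.SpinSystem([zr.Spin("A", 1.0, 2.0, 1.0)], [], name="single")


@pytest.fixture
def ax_pair():
    """Weakly coupled AX pair, J = 7 Hz, negligible relaxation."""
    return zr.SpinSystem(
        [zr.Spin("I", 0.5, 1e9, 1e9), zr.Spin("S", 1.5, 1e9, 1e9)],
        [zr.Coupling("I", "S", 7.0)],
        name="ax",
    )


@pytest.fixture
def homogeneous_field():
    return zr.FieldModel(n_z=1, carrier_ppm=0.0)


@pytest.fixture
def pulse():
    return zr.SlicePulse()


@pytest.fixture
def zs_acq():
    return zr.ZSAcquisition(n_chunks=10, spectral_width_hz=2000.0)


@pytest.fixture
def bromobutane_bundle():
    return zr.reference_schemes()["bromobutane"]


@pytest.fixture
def quinine_bundle():
    return zr.reference_schemes()["quinine"]
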