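import math

import pytest

from lvmass import (
    DiscStack,
    LinearMeasurements,
    PhantomSpec,
    SaxTrace,
)
from lvmass.phantom import Shape


@pytest.fixture
def linear_default() -> LinearMeasurements:
    return LinearMeasurements(ivs_cm=1.0, lvid_cm=4.5, pwt_cm=1.0)


@pytest.fixture
def cylinder_stack() -> DiscStack:
    """Cylindrical cavity, radius 2 cm, length 8 cm, 30 discs."""
    return DiscStack(
        semi_axes=tuple((2.0, 2.0) for _ in range(30)),
        length_4ch_cm=8.0,
        length_2ch_cm=8.0,
    )


@pytest.fixture
def sax_concentric() -> SaxTrace:
    """Concentric circles, radii 3 and 2 cm -> t = 1 cm exactly."""
    return SaxTrace(a1_cm2=9.0 * math.pi, a2_cm2=4.0 * math.pi)


@pytest.fixture
def hemi_phantom() -> PhantomSpec:
    """Default hemi-ellipsoid: cavity length 8, semi-axes 2.5/2.5, wall 1."""
    return PhantomSpec()


@pytest.fixture
def bulge_phantom() -> PhantomSpec:
    """Circular cylinder with a focal septal thickening at the SAX level."""
    return PhantomSpec(
        shape=Shape.SEPTAL_BULGE,
        endo_long_cm=8.0,
        endo_b_cm=2.0,
        endo_c_cm=2.0,
        wall_cm=1.0,
        bulge_extra_cm=0.8,
    )
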