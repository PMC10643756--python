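import numpy as np
import pytest

from ooplasm.calibration import CalibrationCurve
from ooplasm.synth import SyntheticImageSpec, make_oocyte_image


@pytest.fixture(scope="session")
def linear_curve():
    """Globally linear grey->OD map (slope 4/240 OD per grey, 0 OD at 250)."""
    return CalibrationCurve(tuple(np.linspace(250.0, 10.0, 5)),
                            (0.0, 1.0, 2.0, 3.0, 4.0))


@pytest.fixture
def flat_disk():
    """Noise-free uniform disk: every texture/GRAD feature is degenerate."""
    spec = SyntheticImageSpec(base_grey=120, radial_slope=0.0,
                              texture_sigma=0.0, seed=0)
    return make_oocyte_image(spec)


@pytest.fixture
def gradient_disk(linear_curve):
    """Noise-free disk with a bright centre (negative slope) and truth ODs."""
    spec = SyntheticImageSpec(base_grey=140, radial_slope=-40.0,
                              texture_sigma=0.0, seed=0)
    return make_oocyte_image(spec, curve=linear_curve)
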