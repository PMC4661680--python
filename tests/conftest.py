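import numpy as np
import pytest

from retisim import ChartSpec, build_chart, build_schematic_eye
from retisim.calibrate import build_calibration


@pytest.fixture(scope="session")
def default_eye():
    return build_schematic_eye()


@pytest.fixture(scope="session")
def default_chart():
    return build_chart(ChartSpec())


@pytest.fixture(scope="session")
def one_letter_chart():
    return build_chart(ChartSpec(rows=(("20/200", "E"),)))


@pytest.fixture(scope="session")
def small_curve(default_eye, default_chart):
    """Whole-chart calibration at a modest budget for unit tests."""
    return build_calibration(
        default_eye, default_chart, region="whole", n_rays=20_000, seed=123
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
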