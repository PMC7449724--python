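import numpy as np
import pytest

from thztdd.dielectrics import default_library
from thztdd.geometry import Geometry
from thztdd.synthetic import (
    ExperimentDesign,
    PulseParams,
    default_time_axis,
    reference_pulse,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture(scope="session")
def pulse():
    return reference_pulse(default_time_axis())


@pytest.fixture(scope="session")
def thin_geometry():
    """Thin window so the echo fits in the short test acquisition window."""
    return Geometry(thickness_mm=0.5)


@pytest.fixture(scope="session")
def short_pulse():
    """256-sample trace for fast per-test simulations (25.6 ps window)."""
    return reference_pulse(
        default_time_axis(n=256, dt_ps=0.1), PulseParams(center_ps=4.0)
    )


@pytest.fixture()
def small_design():
    """Five groups, two replicates, 8x8 raster: fast end-to-end fixture."""
    return ExperimentDesign(
        replicates=2, nx=8, ny=8, pitch_mm=0.5, spot_radius_mm=4.0, seed=11
    )


@pytest.fixture(scope="session")
def band_frequencies():
    return np.linspace(0.2, 1.5, 27)
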