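import numpy as np
import pytest

from qusdr.synthetic import (
    AcquisitionGeometry,
    ReferencePhantom,
    ScattererField,
    ellipse_roi,
    make_scatterer_field,
    simulate_reference_frame,
    simulate_rf_frame,
)


@pytest.fixture(scope="session")
def geometry():
    """Clinical acquisition geometry (full sector)."""
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def small_geometry():
    """Small frame for fast unit tests."""
    return AcquisitionGeometry(n_lines=48, lateral_width=0.72, depth=1.5)


@pytest.fixture(scope="session")
def phantom():
    return ReferencePhantom()


@pytest.fixture(scope="session")
def reference_frame(geometry, phantom):
    return simulate_reference_frame(phantom, geometry, seed=100)


@pytest.fixture(scope="session")
def small_reference_frame(small_geometry, phantom):
    return simulate_reference_frame(phantom, small_geometry, seed=100)


@pytest.fixture(scope="session")
def small_roi(small_geometry):
    return ellipse_roi(small_geometry, center_z=0.75, center_x=0.36,
                       semi_z=0.45, semi_x=0.3)


@pytest.fixture(scope="session")
def speckle_frame(small_geometry):
    """Diffuse fully developed speckle frame, matched attenuation."""
    field = make_scatterer_field("random", 20000, geometry=small_geometry,
                                 diameter=30.0, seed=7)
    return simulate_rf_frame(field, small_geometry, 0.576, seed=7)


def single_scatterer_frame(geometry, z_cm, x_cm, attenuation=0.0, **kwargs):
    field = ScattererField(positions=[[z_cm, x_cm]], amplitudes=[1.0],
                           mode="random")
    return simulate_rf_frame(field, geometry, attenuation, noise_floor=None,
                             **kwargs)
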