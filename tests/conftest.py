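import numpy as np
import pytest

from calyxsim import (
    SimConfig,
    ap_waveform,
    generate_active_zone,
    place_channels_exclusion_zone,
)


@pytest.fixture(scope="session")
def az5_like():
    """Synthetic stand-in for the small reference active zone:
    0.05 um^2, 6 docked vesicles (density 120 /um^2)."""
    return generate_active_zone(0.05, 6, seed=42, az_id="az5-like")


@pytest.fixture(scope="session")
def az11_like():
    """Synthetic stand-in for the large reference active zone:
    25/280 um^2, 11 docked vesicles.  The seed is chosen so the map has a
    void space in its bottom half large enough for a 25-channel supercluster
    30 nm clear of every vesicle, matching the described geometry."""
    return generate_active_zone(25 / 280, 11, seed=23, az_id="az11-like")


@pytest.fixture(scope="session")
def standard_ap():
    return ap_waveform()


@pytest.fixture()
def default_config():
    return SimConfig()


@pytest.fixture(scope="session")
def square_az():
    """A 300 x 300 nm square window with one central vesicle."""
    from calyxsim import ActiveZoneMap

    boundary = np.array([[-150, -150], [150, -150], [150, 150], [-150, 150]], float)
    return ActiveZoneMap("square", boundary, np.array([[0.0, 0.0]]))
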