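import numpy as np
import pytest

from fins.image_io import ChannelMapping
from fins.synthetic import FixtureSpec, MarkerSpec, generate_fixture


@pytest.fixture(scope="session")
def small_spec():
    """A quick 192x192 field with 5 clean nuclei for unit tests."""
    return FixtureSpec(
        height=192,
        width=192,
        n_nuclei=5,
        radius_range=(5.0, 9.0),
        noise_sigma=0.0,
        speckle_rate=0.0,
        n_detritus=0,
        border_fraction=0.0,
        taper_px=0.0,
        marker_specs=(
            MarkerSpec("Ki67", positive_fraction=0.4, foci_per_nucleus=2, focus_radius=1.5),
            MarkerSpec("gH2AX", positive_fraction=0.6, foci_per_nucleus=3, focus_radius=1.2),
        ),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_fixture(small_spec):
    return generate_fixture(small_spec)


@pytest.fixture(scope="session")
def two_marker_mapping():
    return ChannelMapping(counterstain_channel=0, marker_channels=((1, "Ki67"), (2, "gH2AX")))


@pytest.fixture
def disk_field():
    """f = -0.5 inside a 20-px-radius disk, +0.5 outside (128x128)."""
    rr, cc = np.mgrid[:128, :128]
    disk = (rr - 64) ** 2 + (cc - 64) ** 2 <= 20**2
    return np.where(disk, -0.5, 0.5), disk
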