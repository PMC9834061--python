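import numpy as np
import pytest

from helicta import (
    FilamentTrace,
    HelicalParams,
    LOKIACTIN_RISE,
    LOKIACTIN_TWIST,
    lokiactin_subunit,
    render_filament,
)

VOX = 5.36  # A/voxel used throughout the filament tests (binning-4-like scale)


@pytest.fixture(scope="session")
def vox():
    return VOX


@pytest.fixture(scope="session")
def loki_params():
    return HelicalParams(LOKIACTIN_RISE, LOKIACTIN_TWIST)


def straight_filament(box, params=None, voxel=VOX, azimuth0=0.0, polarity=1,
                      two_strands=True):
    """Noise-free straight filament through the box center, along z."""
    if params is None:
        params = HelicalParams(LOKIACTIN_RISE, LOKIACTIN_TWIST)
    c = box // 2 * voxel
    half = box * voxel  # extend beyond the box so the helix fills it
    trace = FilamentTrace(0, np.array([[c, c, c - half], [c, c, c + half]]))
    vol, gt = render_filament(
        trace, params, lokiactin_subunit(voxel), (box, box, box), voxel,
        azimuth0=azimuth0, polarity=polarity, two_strands=two_strands,
    )
    return vol, gt


@pytest.fixture(scope="session")
def loki_phantom_64(loki_params):
    """64^3 noise-free two-stranded filament with the refined parameters."""
    vol, _ = straight_filament(64, loki_params)
    return vol


@pytest.fixture(scope="session")
def loki_phantom_48(loki_params):
    vol, _ = straight_filament(48, loki_params)
    return vol
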