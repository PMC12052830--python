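import numpy as np
import pytest

from vortexflux import (
    PhotonModel,
    VortexBeam,
    make_four_point_tcp,
    make_raster_tcp,
)


@pytest.fixture
def beam_l1():
    return VortexBeam(l=1, waist=300.0)


@pytest.fixture
def four_point_model():
    """Reference four-point model: l=1, L=50, N=100, SBR=4, w=300."""
    return PhotonModel(
        beam=VortexBeam(l=1, waist=300.0),
        pattern=make_four_point_tcp(50.0),
        n_photons=100,
        sbr=4.0,
        sbr_mode="all_exposures",
    )


@pytest.fixture
def noiseless_model():
    return PhotonModel(
        beam=VortexBeam(l=1, waist=300.0),
        pattern=make_four_point_tcp(50.0),
        n_photons=100,
        sbr=np.inf,
    )


@pytest.fixture
def raster_model():
    return PhotonModel(
        beam=VortexBeam(l=1, waist=300.0),
        pattern=make_raster_tcp(50.0, dim=4),
        n_photons=100,
        sbr=4.0,
        sbr_mode="all_exposures",
    )
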