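import numpy as np
import pytest

from isofocus import acoustics, gradient, media, transport

UL_PER_MIN = 1e-9 / 60.0


@pytest.fixture(scope="session")
def model():
    return media.MixtureModel.default()


@pytest.fixture(scope="session")
def geom():
    return gradient.ChannelGeometry()


@pytest.fixture(scope="session")
def bead():
    """The 2.23 um polystyrene PIV tracer bead."""
    return media.POLYSTYRENE_BEAD


@pytest.fixture(scope="session")
def medium10(model):
    return model.properties_at(10.0)


@pytest.fixture(scope="session")
def ba_f3(model):
    """BA-F3-like cell: effective impedance 1.68 MPa s m^-1, radius 4 um."""
    return transport.CellModel.from_impedance(
        1.68e6, model, radius=4.0e-6, density=1060.0, label="BA-F3"
    )


@pytest.fixture(scope="session")
def mcf7(model):
    """MCF7-like cell: 1.5x the BA-F3 radius, lower impedance."""
    return transport.CellModel.from_impedance(
        1.63e6, model, radius=6.0e-6, density=1055.0, label="MCF7"
    )


@pytest.fixture
def flow_1to1():
    """8 ul/min total, 1:1 central:side split."""
    return gradient.FlowConfig(total=8 * UL_PER_MIN, central=4 * UL_PER_MIN)


@pytest.fixture
def gradient_profile(flow_1to1, geom):
    """The 10%/36% lamination used for IAP measurements."""
    return gradient.initial_profile(flow_1to1, geom, c_side=10.0, c_center=36.0)


def make_field(geom, e_ac, u0=0.0):
    return acoustics.StandingWaveField.half_wave(geom.width, e_ac, offset_velocity=u0)


@pytest.fixture
def field15(geom):
    return make_field(geom, 15.0)


def sample_at_frames(track, n_frames=30, frame_rate=3.0):
    """Resample a dense simulated track at the stop-flow camera cadence."""
    ts = np.arange(n_frames) / frame_rate
    return transport.Track(
        t=ts, y=np.interp(ts, track.t, track.y), frame_rate=frame_rate, meta=dict(track.meta)
    )
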