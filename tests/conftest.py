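import numpy as np
import pytest

from ehtkit import synthetic_data as sd


@pytest.fixture(scope="session")
def plane_movie_25():
    """Noiseless plane-wave movie at 25 cm/s on the photodiode geometry."""
    cfg = sd.WaveSimConfig(cv_true=25.0, noise_sd=0.0, seed=0)
    return sd.gen_wave_movie(cfg)


@pytest.fixture(scope="session")
def point_movie_40():
    """Noiseless corner point-source movie at 40 cm/s on the camera geometry."""
    g = sd.CAMERA_GEOMETRY
    cfg = sd.WaveSimConfig(
        rows=g["rows"],
        cols=g["cols"],
        pixel_size=g["pixel_size"],
        dt=g["dt"],
        duration=700.0,
        source="point",
        origin_rc=(0, 0),
        cv_true=40.0,
        ap=sd.APTemplate(upstroke=20.0),
        noise_sd=0.0,
    )
    return sd.gen_wave_movie(cfg)


@pytest.fixture(scope="session")
def vessel_phantom():
    """Single diagonal vessel, noiseless."""
    seg = sd.VesselSegment(p0=(10, 5), p1=(80, 90), radius=3.0)
    cfg = sd.VesselPhantomConfig(vessels=[seg], noise_sd=0.0, seed=0)
    return sd.gen_hyperspectral_phantom(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(0)
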