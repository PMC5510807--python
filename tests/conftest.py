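import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ciliaflow as cf

settings.register_profile(
    "default", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_wall():
    """Horizontal 5-point wall for the compact test movies (51.2 μm wide)."""
    x = np.linspace(0.0, 160 * 0.32, 5)
    return cf.EdgePolyline(np.column_stack([x, np.full(5, 24.0)]))


def make_small_spec(wall, **overrides):
    kwargs = dict(
        edge_polyline=wall, n_frames=512, height=96, width=160,
        cbf=14.0, wavelength=13.0, cilia_density=0.84,
        profile=(138.3, 30.0), rng_seed=7)
    kwargs.update(overrides)
    return cf.SyntheticMovieSpec(**kwargs)


@pytest.fixture(scope="session")
def small_spec(small_wall):
    return make_small_spec(
        small_wall, bead_entries=[(0, 8.0), (40, 14.0)])


@pytest.fixture(scope="session")
def small_movie(small_spec):
    return cf.generate_movie(small_spec)


@pytest.fixture(scope="session")
def full_wall():
    """Wall for the reference-size movie (256×192 px field of view)."""
    return cf.default_edge_polyline()


@pytest.fixture(scope="session")
def full_spec(full_wall):
    return cf.SyntheticMovieSpec(
        edge_polyline=full_wall,
        bead_entries=[(0, 8.0), (100, 15.0), (0, 25.0), (200, 40.0)],
        rng_seed=11)


@pytest.fixture(scope="session")
def full_movie(full_spec):
    return cf.generate_movie(full_spec)


@pytest.fixture(scope="session")
def patient1_config():
    """Envelope-model parameters of a well-beating reference edge."""
    return cf.EnvelopeModelConfig.from_beat_params(
        cbf=14.0, cba=7.5, wavelength=13.0, h=87.5, rho_c=0.84)
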