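import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flim4.meta import AcquisitionMeta, delta_irf, gaussian_irf
from flim4.synth import load_baseline, make_geometry, simulate_decay_cube

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def meta():
    """64 x 64 tile at the native 0.41 um pitch, full TCSPC timing."""
    return AcquisitionMeta().tile(64)


@pytest.fixture(scope="session")
def irf(meta):
    return gaussian_irf(meta)


@pytest.fixture(scope="session")
def dirac(meta):
    return delta_irf(meta)


@pytest.fixture(scope="session")
def baseline():
    return load_baseline()


@pytest.fixture(scope="session")
def adipocyte_cube(meta, irf, baseline):
    """One default-scenario synthetic adipocyte acquisition."""
    geom = make_geometry(meta, seed=11)
    cube = simulate_decay_cube(
        geom, baseline, irf, meta, photons_per_pixel=500.0, seed=12
    )
    return cube, geom


@pytest.fixture(scope="session")
def adipocyte_fit(adipocyte_cube):
    """The default cube fitted at 3x3 binning (shared: fitting is the
    expensive step)."""
    from flim4.decay import fit_image

    cube, geom = adipocyte_cube
    return fit_image(cube, k=3), geom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
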