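import numpy as np
import pytest

from uro3d import PhantomSpec, generate_labels, simulate_frames
from uro3d.geometry import AcquisitionGeometry

# Small, fast phantom geometry shared by many tests: the reference 35 mm
# sweep kinematics at a reduced frame rate and frame size.
SMALL_GEOMETRY = AcquisitionGeometry(
    travel_mm=35.0, scan_time_s=21.0, frame_rate_hz=6.0, pixel_mm=(0.15, 0.15)
)


@pytest.fixture(scope="session")
def small_geometry():
    return SMALL_GEOMETRY


@pytest.fixture(scope="session")
def noiseless_spec():
    return PhantomSpec(
        geometry=SMALL_GEOMETRY,
        frame_shape=(96, 96),
        stricture_length_mm=14.0,
        stricture_depth=0.8,
        speckle_sigma=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def noiseless_labels(noiseless_spec):
    return generate_labels(noiseless_spec)


@pytest.fixture(scope="session")
def noiseless_stack(noiseless_spec, noiseless_labels):
    return simulate_frames(noiseless_labels, noiseless_spec)


@pytest.fixture(scope="session")
def noisy_spec():
    return PhantomSpec(
        geometry=SMALL_GEOMETRY,
        frame_shape=(96, 96),
        stricture_length_mm=14.0,
        stricture_depth=0.8,
        seed=0,
    )


@pytest.fixture(scope="session")
def noisy_labels(noisy_spec):
    return generate_labels(noisy_spec)


@pytest.fixture(scope="session")
def noisy_stack(noisy_spec, noisy_labels):
    return simulate_frames(noisy_labels, noisy_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
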