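import numpy as np
import pytest

from parm import synthetic


@pytest.fixture(scope="session")
def tiny_acq():
    """Short clean acquisition for fast unit tests (64x64, 200 frames)."""
    return synthetic.AcquisitionSpec(n_frames=200, shape=(64, 64),
                                     psf_sigma=0.1, rng_seed=1)


@pytest.fixture(scope="session")
def horizontal_sim(tiny_acq):
    """One straight horizontal streamline at 10 mm/s (0.4 px/frame)."""
    spec = synthetic.StreamlineSpec(
        control_points=((0.3, 1.6), (2.9, 1.6)), speed=10.0, mb_rate=20.0)
    return synthetic.simulate([spec], tiny_acq)


@pytest.fixture(scope="session")
def cluttered_sim():
    """Three-streamline phantom with rank-2 clutter and noise, 300 frames."""
    acq = synthetic.AcquisitionSpec(
        n_frames=300, shape=(128, 128), psf_sigma=0.1, noise_sigma=0.01,
        clutter_rank=2, clutter_amplitude=0.5, rng_seed=7)
    specs = [
        synthetic.StreamlineSpec(control_points=((0.5, 2.0), (5.9, 2.0)),
                                 speed=2.0, mb_rate=20.0),
        synthetic.StreamlineSpec(control_points=((5.9, 4.0), (0.5, 4.0)),
                                 speed=8.0, mb_rate=20.0),
        synthetic.StreamlineSpec(control_points=((3.2, 0.5), (3.2, 5.9)),
                                 speed=5.0, mb_rate=20.0),
    ]
    return synthetic.simulate(specs, acq)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
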