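import numpy as np
import pytest

from lungdce import (
    AcquisitionConfig,
    KineticGroundTruth,
    make_phantom,
    render_dce,
)
from lungdce.synthetic import gamma_variate_aif

SIDE_PBF = {"left": 60.4, "right": 90.0}
SIDE_MTT = {"left": 6.3, "right": 6.0}


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom((32, 32, 32), affected_side="left", seed=11)


@pytest.fixture(scope="session")
def truth32(phantom32):
    return KineticGroundTruth.from_side_values(phantom32, pbf=SIDE_PBF, mtt=SIDE_MTT)


@pytest.fixture(scope="session")
def noiseless_acq():
    return AcquisitionConfig(noise_sigma=0.0, seed=21)


@pytest.fixture(scope="session")
def noiseless_series(phantom32, truth32, noiseless_acq):
    return render_dce(phantom32, truth32, noiseless_acq)


@pytest.fixture(scope="session")
def noisy_series(phantom32, truth32):
    acq = AcquisitionConfig(noise_sigma=1.0, seed=22)
    return render_dce(phantom32, truth32, acq)


def prompt_bolus(n_frames: int = 40, dt: float = 1.5) -> np.ndarray:
    """AIF whose bolus peaks at the first frame (t0 = -alpha*beta), giving a
    well-conditioned, nonsingular (triangular-solvable) Toeplitz operator."""
    t = np.arange(n_frames) * dt
    return gamma_variate_aif(t, t0=-4.5, alpha=3.0, beta=1.5, amplitude=1.0)


@pytest.fixture()
def prompt_aif():
    return prompt_bolus()
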