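import numpy as np
import pytest

from smiledyn.landmark_io import (
    LEFT_LIP_CORNER,
    N_LANDMARKS,
    RIGHT_LIP_CORNER,
    LandmarkSequence,
)


def trapezoid(n_rise=50, n_plateau=100, n_fall=50, amplitude=10.0, residual=0.0):
    """Noise-free rise/plateau/fall displacement signal.

    With the defaults: linear 0->10 over frames 0-49, plateau at 10 over
    frames 50-149, linear fall back to ``residual`` over frames 150-199.
    """
    rise = np.linspace(0.0, amplitude, n_rise, endpoint=False)
    plateau = np.full(n_plateau, amplitude)
    fall = np.linspace(amplitude, residual, n_fall + 1)[1:]
    return np.concatenate([rise, plateau, fall])


def corner_sequence(d_right, d_left=None, frame_rate_hz=50.0):
    """68-point sequence whose lip corners travel the given scalar distances
    along fixed unit directions; every other landmark is static."""
    d_right = np.asarray(d_right, dtype=float)
    d_left = d_right if d_left is None else np.asarray(d_left, dtype=float)
    n = len(d_right)
    coords = np.zeros((n, N_LANDMARKS, 3))
    coords[:] = np.linspace(0, 1, N_LANDMARKS)[None, :, None]  # distinct rest points
    dir_r = np.array([-0.6, -0.8, 0.0])
    dir_l = np.array([0.6, -0.8, 0.0])
    coords[:, RIGHT_LIP_CORNER, :] = np.array([-25.0, 40.0, 6.0]) + d_right[:, None] * dir_r
    coords[:, LEFT_LIP_CORNER, :] = np.array([25.0, 40.0, 6.0]) + d_left[:, None] * dir_l
    return LandmarkSequence(coords, frame_rate_hz=frame_rate_hz)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
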