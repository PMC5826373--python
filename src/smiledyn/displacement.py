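"""Scalar lip-corner displacement signals from corrected landmark sequences.

Three ways of collapsing the two lip-corner trajectories into one intensity
signal D(t) are provided:

``from_rest`` (default)
    Mean Euclidean distance of each lip corner from its own first-frame
    (neutral) position.  Units follow the coordinates (mm in 3D, px in 2D).
``half_width``
    Distance from the per-frame lip midpoint to the right corner, i.e. half
    the instantaneous lip width.  A lip-width proxy: it responds to mouth
    widening but not to a symmetric upward pull.
``midpoint_normalized``
    Mean corner distance from the *first-frame* lip midpoint, divided by the
    first-frame lip width.  Dimensionless and therefore scale-invariant.

Episodes are assumed to begin at (near-)neutral expression, so frame 1 is the
rest reference; for non-neutral starts the reference can be switched to the
minimum-displacement frame.  Per-side signals D_L and D_R are always the
per-corner distance from that corner's own reference position, whatever the
pooled method, so that the symmetry features compare genuinely independent
left/right measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmark_io import LEFT_LIP_CORNER, RIGHT_LIP_CORNER, LandmarkSequence

METHODS = ("from_rest", "half_width", "midpoint_normalized")


@dataclass
class DisplacementSignal:
    """Per-frame pooled and per-side lip-corner displacement."""

    d: np.ndarray
    d_left: np.ndarray
    d_right: np.ndarray
    frame_rate_hz: float
    method: str

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.d_left = np.asarray(self.d_left, dtype=float)
        self.d_right = np.asarray(self.d_right, dtype=float)
        if not (len(self.d) == len(self.d_left) == len(self.d_right)):
            raise ValueError("pooled and per-side signals must have equal length")

    @property
    def n_frames(self) -> int:
        return len(self.d)


def _corners(seq: LandmarkSequence) -> tuple[np.ndarray, np.ndarray]:
    return seq.coords[:, RIGHT_LIP_CORNER, :], seq.coords[:, LEFT_LIP_CORNER, :]


def _per_side_from_rest(seq: LandmarkSequence, reference_frame: int) -> tuple[np.ndarray, np.ndarray]:
    right, left = _corners(seq)
    d_right = np.linalg.norm(right - right[reference_frame], axis=1)
    d_left = np.linalg.norm(left - left[reference_frame], axis=1)
    return d_left, d_right


def displacement_from_rest(seq: LandmarkSequence, reference_frame: int = 0) -> DisplacementSignal:
    """D(t) = [rho(r_ref, r_t) + rho(l_ref, l_t)] / 2 for the two lip corners."""
    if seq.n_frames < 2:
        raise ValueError("need at least two frames to measure movement from rest")
    d_left, d_right = _per_side_from_rest(seq, reference_frame)
    return DisplacementSignal(
        d=(d_left + d_right) / 2.0,
        d_left=d_left,
        d_right=d_right,
        frame_rate_hz=seq.frame_rate_hz,
        method="from_rest",
    )


def displacement_half_width(seq: LandmarkSequence) -> DisplacementSignal:
    """D(t) = rho(midpoint_t, right corner_t): half the instantaneous lip width."""
    right, left = _corners(seq)
    mid = (right + left) / 2.0
    d = np.linalg.norm(right - mid, axis=1)
    d_left, d_right = _per_side_from_rest(seq, 0)
    return DisplacementSignal(d, d_left, d_right, seq.frame_rate_hz, "half_width")


def displacement_midpoint_normalized(seq: LandmarkSequence) -> DisplacementSignal:
    """Mean corner distance from the first-frame midpoint over first-frame lip width.

    At the reference frame itself each corner sits half a lip width from the
    midpoint, so the signal starts at 0.5, not 0.
    """
    right, left = _corners(seq)
    mid0 = (right[0] + left[0]) / 2.0
    width0 = np.linalg.norm(right[0] - left[0])
    if width0 == 0.0:
        raise ValueError("zero lip width at reference frame; cannot normalize")
    d = (
        np.linalg.norm(right - mid0, axis=1) + np.linalg.norm(left - mid0, axis=1)
    ) / (2.0 * width0)
    d_left, d_right = _per_side_from_rest(seq, 0)
    return DisplacementSignal(d, d_left, d_right, seq.frame_rate_hz, "midpoint_normalized")


def compute_displacement(
    seq: LandmarkSequence, method: str = "from_rest", reference_frame: int | str = 0
) -> DisplacementSignal:
    """Dispatch on method name; see module docstring for the variants.

    ``reference_frame`` applies to ``from_rest`` only; pass ``"min"`` to use
    the minimum-lip-width frame as rest for episodes with non-neutral starts
    (a smile widens the mouth, so the narrowest frame is the most neutral).
    """
    if method == "from_rest":
        if reference_frame == "min":
            probe = displacement_half_width(seq)
            reference_frame = int(np.argmin(probe.d))
        return displacement_from_rest(seq, int(reference_frame))
    if method == "half_width":
        return displacement_half_width(seq)
    if method == "midpoint_normalized":
        return displacement_midpoint_normalized(seq)
    raise ValueError(f"unknown displacement method {method!r}; choose from {METHODS}")
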