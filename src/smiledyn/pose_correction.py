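"""Rigid head-motion removal for 3D landmark sequences.

Head rotation is undone by post-multiplying each frame's landmark row vectors
with the inverse rotations, l'' = l Rx(-pitch) Ry(-yaw) Rz(-roll), and head
translation is removed by re-expressing every landmark relative to a stable
anchor point (the inner nostril, which unlike the inner eye corners is not
perturbed by blinks).  After both steps, lip-corner motion reflects facial
action only: the whole correction is invariant to any rigid rotation plus
translation applied uniformly to the raw sequence.

2D (image-plane) sequences get only the anchoring step; a planar projection
cannot be un-rotated without depth.
"""

from __future__ import annotations

import numpy as np

from .landmark_io import ANCHOR_NOSTRIL, HeadPose, LandmarkSequence

_AXES = {"x": 0, "y": 1, "z": 2}


def rotation_matrix(axis: str, angle: float) -> np.ndarray:
    """Right-handed 3x3 rotation about the named axis (angle in radians)."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    c, s = np.cos(angle), np.sin(angle)
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, s], [0.0, -s, c]])
    if axis == "y":
        return np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


def correct_rotation(seq: LandmarkSequence, pose: HeadPose) -> LandmarkSequence:
    """Undo per-frame head rotation on a 3D sequence.

    Each frame's landmarks (row vectors) are post-multiplied by
    Rx(-pitch) . Ry(-yaw) . Rz(-roll), in that order.  Applying the correction
    twice with the same pose does *not* return the input: the operation is an
    inverse, not a projection.
    """
    if seq.dims != 3:
        raise ValueError("rotation correction requires a 3D sequence")
    if pose.n_frames != seq.n_frames:
        raise ValueError("pose and sequence lengths differ")
    out = np.empty_like(seq.coords)
    for t in range(seq.n_frames):
        correction = (
            rotation_matrix("x", -pose.pitch[t])
            @ rotation_matrix("y", -pose.yaw[t])
            @ rotation_matrix("z", -pose.roll[t])
        )
        out[t] = seq.coords[t] @ correction
    return LandmarkSequence(out, seq.frame_rate_hz, seq.valid.copy())


def apply_rotation(seq: LandmarkSequence, pose: HeadPose) -> LandmarkSequence:
    """Forward rotation (the motion that :func:`correct_rotation` undoes).

    Post-multiplies by Rz(roll) . Ry(yaw) . Rx(pitch), the exact inverse of
    the correction product, so correct(apply(seq)) == seq.
    """
    if seq.dims != 3:
        raise ValueError("rotation requires a 3D sequence")
    out = np.empty_like(seq.coords)
    for t in range(seq.n_frames):
        forward = (
            rotation_matrix("z", pose.roll[t])
            @ rotation_matrix("y", pose.yaw[t])
            @ rotation_matrix("x", pose.pitch[t])
        )
        out[t] = seq.coords[t] @ forward
    return LandmarkSequence(out, seq.frame_rate_hz, seq.valid.copy())


def center_on_anchor(seq: LandmarkSequence, anchor: int = ANCHOR_NOSTRIL) -> LandmarkSequence:
    """Express every landmark relative to the per-frame anchor point.

    Maps the anchor itself to the origin in every frame, which removes any
    global translation of the head (the anchor is configurable; the default is
    the inner nostril of the 68-point scheme).
    """
    out = seq.coords - seq.coords[:, anchor : anchor + 1, :]
    return LandmarkSequence(out, seq.frame_rate_hz, seq.valid.copy())


def correct(seq: LandmarkSequence, pose: HeadPose | None, anchor: int = ANCHOR_NOSTRIL) -> LandmarkSequence:
    """Full head-motion correction: rotation (3D only) then anchoring."""
    if seq.dims == 3:
        if pose is None:
            raise ValueError("3D correction requires head-pose angles")
        seq = correct_rotation(seq, pose)
    return center_on_anchor(seq, anchor=anchor)
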