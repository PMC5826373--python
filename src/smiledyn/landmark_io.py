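"""Reading and writing facial-landmark time series and per-episode feature tables.

The on-disk landmark format is the OpenFace 0.3.0 CSV dialect: one row per
video frame with ``frame``, ``success``, head-pose columns ``pose_Rx`` /
``pose_Ry`` / ``pose_Rz`` (radians), and 68-point landmark columns —
``x_0..x_67`` / ``y_0..y_67`` for 2D pixel coordinates and
``X_0..X_67`` / ``Y_0..Y_67`` / ``Z_0..Z_67`` for 3D world coordinates (mm).

Landmark numbering: the classic 68-point annotation scheme is 1-based in most
of the facial-expression literature, while OpenFace columns are 0-based.  The
inner-nostril anchor ("point 34") is column index 33; the right and left lip
corners ("points 49" and "55") are column indices 48 and 54.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 0-based column indices for the landmarks the pipeline uses.
ANCHOR_NOSTRIL = 33
RIGHT_LIP_CORNER = 48
LEFT_LIP_CORNER = 54

N_LANDMARKS = 68


class FormatError(ValueError):
    """A landmark CSV does not conform to the expected dialect."""


class QCError(RuntimeError):
    """An episode fails a hard quality gate before feature extraction."""


@dataclass
class LandmarkSequence:
    """Per-frame 68-point landmark coordinates.

    coords has shape ``(n_frames, 68, dims)`` with dims 2 (pixels) or
    3 (world mm).  ``valid`` marks frames where landmark detection succeeded.
    """

    coords: np.ndarray
    frame_rate_hz: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != N_LANDMARKS:
            raise ValueError(
                f"coords must be (n_frames, {N_LANDMARKS}, dims); got {self.coords.shape}"
            )
        if self.coords.shape[2] not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")
        if not self.frame_rate_hz > 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.valid is None:
            self.valid = np.ones(self.n_frames, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.n_frames,):
            raise ValueError("valid must have one flag per frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dims(self) -> int:
        return self.coords.shape[2]


@dataclass
class HeadPose:
    """Per-frame head rotation angles in radians: pitch, yaw, roll."""

    pitch: np.ndarray
    yaw: np.ndarray
    roll: np.ndarray

    def __post_init__(self) -> None:
        self.pitch = np.asarray(self.pitch, dtype=float)
        self.yaw = np.asarray(self.yaw, dtype=float)
        self.roll = np.asarray(self.roll, dtype=float)
        n = self.pitch.shape[0]
        if self.yaw.shape != (n,) or self.roll.shape != (n,):
            raise ValueError("pitch, yaw, roll must have equal length")

    @property
    def n_frames(self) -> int:
        return self.pitch.shape[0]


def _landmark_columns(mode: str) -> list[str]:
    if mode == "2d":
        axes = ("x", "y")
    elif mode == "3d":
        axes = ("X", "Y", "Z")
    else:
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    return [f"{ax}_{i}" for ax in axes for i in range(N_LANDMARKS)]


def read_openface_csv(
    path, mode: str = "3d", frame_rate_hz: float = 50.0
) -> tuple[LandmarkSequence, HeadPose]:
    """Read an OpenFace-dialect landmark CSV.

    Frames with ``success == 0`` are flagged invalid but their coordinates are
    retained.  Raises :class:`FormatError` naming the first missing column.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty landmark file: {path}") from exc
    # real OpenFace output pads column names with spaces
    df.columns = [c.strip() for c in df.columns]
    if len(df) == 0:
        raise FormatError(f"landmark file has a header but no frames: {path}")

    needed = ["frame", "success", "pose_Rx", "pose_Ry", "pose_Rz"]
    needed += _landmark_columns(mode)
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")

    frames = df["frame"].to_numpy()
    if np.any(np.diff(frames) <= 0):
        raise FormatError(f"frame index not strictly increasing in {path}")

    cols = _landmark_columns(mode)
    dims = 2 if mode == "2d" else 3
    coords = (
        df[cols].to_numpy(dtype=float).reshape(len(df), dims, N_LANDMARKS)
    ).transpose(0, 2, 1)
    valid = df["success"].to_numpy(dtype=float) != 0
    seq = LandmarkSequence(coords, frame_rate_hz=frame_rate_hz, valid=valid)
    pose = HeadPose(
        pitch=df["pose_Rx"].to_numpy(dtype=float),
        yaw=df["pose_Ry"].to_numpy(dtype=float),
        roll=df["pose_Rz"].to_numpy(dtype=float),
    )
    return seq, pose


def write_landmark_csv(path, seq: LandmarkSequence, pose: HeadPose) -> None:
    """Write a landmark sequence (and head pose) in the OpenFace dialect.

    A 3D sequence also emits 2D ``x_i``/``y_i`` columns as the orthographic
    projection (X, Y), mirroring how OpenFace's 3D model relates to the image
    plane; a 2D sequence emits only 2D columns.
    """
    if pose.n_frames != seq.n_frames:
        raise ValueError("pose and sequence lengths differ")
    data: dict[str, np.ndarray] = {
        "frame": np.arange(1, seq.n_frames + 1),
        "success": seq.valid.astype(int),
        "pose_Rx": pose.pitch,
        "pose_Ry": pose.yaw,
        "pose_Rz": pose.roll,
    }
    for d, ax in enumerate("xy"):
        for i in range(N_LANDMARKS):
            data[f"{ax}_{i}"] = seq.coords[:, i, d]
    if seq.dims == 3:
        for d, ax in enumerate("XYZ"):
            for i in range(N_LANDMARKS):
                data[f"{ax}_{i}"] = seq.coords[:, i, d]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def interpolate_invalid(seq: LandmarkSequence, max_gap: int = 5) -> LandmarkSequence:
    """Fill failed-detection frames by linear interpolation from valid neighbours.

    Runs of more than ``max_gap`` consecutive invalid frames (or invalid frames
    at the sequence boundary longer than that) abort the episode with
    :class:`QCError`: long tracking dropouts cannot be reconstructed.
    """
    valid = seq.valid
    if valid.all():
        return seq
    if not valid.any():
        raise QCError("no valid frames in episode")
    # longest invalid run
    run = best = 0
    for v in valid:
        run = 0 if v else run + 1
        best = max(best, run)
    if best > max_gap:
        raise QCError(f"invalid-frame run of {best} exceeds max gap {max_gap}")
    idx = np.arange(seq.n_frames)
    coords = seq.coords.copy()
    flat = coords.reshape(seq.n_frames, -1)
    for j in range(flat.shape[1]):
        flat[~valid, j] = np.interp(idx[~valid], idx[valid], flat[valid, j])
    return LandmarkSequence(
        flat.reshape(seq.coords.shape), seq.frame_rate_hz, np.ones(seq.n_frames, bool)
    )


# ---------------------------------------------------------------------------
# feature tables

def write_features_table(records, path) -> None:
    """Write one row per episode: subject, condition, QC status, 17 features.

    ``records`` is a non-empty iterable of dicts as produced by
    :func:`smiledyn.pipeline.episode_record`.
    """
    from .features import FEATURE_NAMES

    records = list(records)
    if not records:
        raise ValueError("no records to write")
    rows = []
    for rec in records:
        if not str(rec.get("condition", "")).strip():
            raise ValueError(f"record has empty condition field: {rec}")
        row = {
            "subject": rec["subject"],
            "condition": rec["condition"],
            "qc_keep": bool(rec.get("qc_keep", True)),
            "qc_reason": rec.get("qc_reason", ""),
        }
        for name in FEATURE_NAMES:
            row[name] = rec[name]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_features_table(path) -> pd.DataFrame:
    from .features import FEATURE_NAMES

    df = pd.read_csv(path)
    for col in ("subject", "condition", *FEATURE_NAMES):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    if df["condition"].isna().any() or (df["condition"].astype(str).str.strip() == "").any():
        raise ValueError(f"empty condition field in {path}")
    return df
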