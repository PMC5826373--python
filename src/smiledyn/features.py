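"""The 17-variable dynamic feature battery for one segmented smile episode.

Durations and ratios come straight from the phase frame counts; speeds are
mean rise / fall rates over the onset and offset phases; the two irregularity
measures capture how unsteady the episode is (rate of prominent peaks, and
the SD of displacement across the apex plateau); the four symmetry measures
compare the left and right lip-corner signals (correlation, apex intensity
difference, and signed / absolute onset-frame lag).

All features are computed on the smoothed displacement signal so that
feature values and segmentation boundaries refer to the same series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

from .displacement import DisplacementSignal
from .segmentation import (
    ExtremaSet,
    NoSmileError,
    PhaseSegmentation,
    find_extrema,
    segment_phases,
    smooth,
)

#: Canonical feature ordering used by every table this package writes.
FEATURE_NAMES = (
    "onset_duration",
    "offset_duration",
    "apex_duration",
    "total_duration",
    "onset_ratio",
    "offset_ratio",
    "apex_ratio",
    "offset_displacement",
    "max_displacement",
    "onset_speed",
    "offset_speed",
    "irregularity_a",
    "irregularity_b",
    "symmetry_a",
    "symmetry_b",
    "symmetry_c",
    "symmetry_d",
)


@dataclass
class SmileFeatures:
    onset_duration: float
    offset_duration: float
    apex_duration: float
    total_duration: float
    onset_ratio: float
    offset_ratio: float
    apex_ratio: float
    offset_displacement: float
    max_displacement: float
    onset_speed: float
    offset_speed: float
    irregularity_a: float
    irregularity_b: float
    symmetry_a: float
    symmetry_b: float
    symmetry_c: float
    symmetry_d: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES], dtype=float)


def durations(seg: PhaseSegmentation) -> dict[str, float]:
    """Phase durations in seconds and their fractions of the whole smile."""
    r = seg.frame_rate_hz
    total = seg.n_total
    return {
        "onset_duration": seg.n_onset / r,
        "apex_duration": seg.n_apex / r,
        "offset_duration": seg.n_offset / r,
        "total_duration": total / r,
        "onset_ratio": seg.n_onset / total,
        "apex_ratio": seg.n_apex / total,
        "offset_ratio": seg.n_offset / total,
    }


def displacement_features(d: np.ndarray, seg: PhaseSegmentation) -> dict[str, float]:
    """Peak displacement over the smile, and the residual at the offset frame.

    The residual ("trace of a smile") is the displacement where the
    expression ends, which for spontaneous smiles often does not return to 0.
    """
    return {
        "max_displacement": float(np.max(d[seg.smile_slice()])),
        "offset_displacement": float(d[seg.offset_frame]),
    }


def speeds(d: np.ndarray, seg: PhaseSegmentation) -> dict[str, float]:
    """Mean rise rate over the onset and mean fall rate over the offset.

    Onset speed sums the positive frame-to-frame increments between the onset
    frame and the apex start, divided by the onset duration in seconds (and
    symmetrically for the offset with falling increments), giving signal
    units per second.  A zero-length phase leaves the speed undefined (NaN).
    """
    r = seg.frame_rate_hz
    out: dict[str, float] = {}
    if seg.n_onset > 0:
        inc = np.diff(d[seg.onset_frame : seg.apex_start + 1])
        out["onset_speed"] = float(inc[inc > 0].sum() / (seg.n_onset / r))
    else:
        out["onset_speed"] = math.nan
    if seg.n_offset > 0:
        dec = np.diff(d[seg.apex_end : seg.offset_frame + 1])
        out["offset_speed"] = float(-dec[dec < 0].sum() / (seg.n_offset / r))
    else:
        out["offset_speed"] = math.nan
    return out


def irregularity_a(
    d: np.ndarray,
    seg: PhaseSegmentation,
    extrema: ExtremaSet | None = None,
    prominence_frac: float = 0.1,
) -> float:
    """Rate of prominent peaks (peaks per second) across the smile.

    A peak counts only when its topographic prominence (height above the
    deepest valley separating it from the nearest higher peak, on its lower
    side) exceeds ``prominence_frac`` of D_max.  Insignificant ripple is
    thereby merged into the peak that dominates it rather than counted, while
    the dominant smile peak always survives.  The count is divided by the
    smile duration in seconds.
    """
    from scipy.signal import peak_prominences

    if extrema is None:
        extrema = find_extrema(d)
    in_span = [
        start + int(np.argmax(d[start : end + 1]))  # the run's summit sample
        for (start, end) in extrema.peak_runs
        if seg.onset_frame <= start <= seg.offset_frame
    ]
    if not in_span:
        return 0.0
    prominences = peak_prominences(d, np.asarray(in_span, dtype=int))[0]
    count = int(np.sum(prominences > prominence_frac * seg.d_max))
    return count / (seg.n_total / seg.frame_rate_hz)


def irregularity_b(d: np.ndarray, seg: PhaseSegmentation) -> float:
    """Sample SD of the displacement across the apex phase.

    Close to zero for a plateau-like apex; large when intensity fluctuates
    before the offset begins.  A one-frame apex has no spread, hence 0.
    """
    apex = d[seg.apex_slice()]
    if len(apex) < 2:
        return 0.0
    return float(np.std(apex, ddof=1))


def symmetry(
    d_left: np.ndarray,
    d_right: np.ndarray,
    seg_left: PhaseSegmentation,
    seg_right: PhaseSegmentation,
    window: str = "union",
) -> dict[str, float]:
    """Four left/right asymmetry measures from independently segmented sides.

    symmetry_a   Pearson correlation of the two signals over the union of the
                 two smile spans (or the full episode with ``window="full"``);
                 NaN when either side has zero variance there.
    symmetry_b   mean right-apex displacement minus mean left-apex displacement.
    symmetry_c   right onset frame minus left onset frame (positive: the right
                 corner starts later), in frames.
    symmetry_d   absolute value of symmetry_c.  Both c and d are reverse-scored:
                 larger means more asymmetric.
    """
    if window == "union":
        lo = min(seg_left.onset_frame, seg_right.onset_frame)
        hi = max(seg_left.offset_frame, seg_right.offset_frame)
    elif window == "full":
        lo, hi = 0, len(d_left) - 1
    else:
        raise ValueError(f"window must be 'union' or 'full', got {window!r}")
    xl = d_left[lo : hi + 1]
    xr = d_right[lo : hi + 1]
    if np.std(xl) == 0.0 or np.std(xr) == 0.0:
        sym_a = math.nan
    else:
        sym_a = float(np.corrcoef(xl, xr)[0, 1])
    sym_b = float(
        np.mean(d_right[seg_right.apex_slice()]) - np.mean(d_left[seg_left.apex_slice()])
    )
    sym_c = float(seg_right.onset_frame - seg_left.onset_frame)
    return {
        "symmetry_a": sym_a,
        "symmetry_b": sym_b,
        "symmetry_c": sym_c,
        "symmetry_d": abs(sym_c),
    }


def extract_features(
    sig: DisplacementSignal,
    smoothing_window: int = 3,
    apex_frac: float = 0.7,
    onset_frac: float = 0.2,
    prominence_frac: float = 0.1,
    symmetry_window: str = "union",
) -> tuple[SmileFeatures, PhaseSegmentation]:
    """Smooth, segment and featurize one episode's displacement signal.

    The pooled signal drives the segmentation and all non-symmetry features;
    the per-side signals are smoothed and segmented independently for the
    symmetry block.  If a side cannot be segmented (e.g. one corner barely
    moves) the symmetry features are NaN rather than the episode failing.
    """
    d = smooth(sig.d, smoothing_window)
    seg = segment_phases(d, sig.frame_rate_hz, apex_frac=apex_frac, onset_frac=onset_frac)
    vals: dict[str, float] = {}
    vals.update(durations(seg))
    vals.update(displacement_features(d, seg))
    vals.update(speeds(d, seg))
    vals["irregularity_a"] = irregularity_a(d, seg, prominence_frac=prominence_frac)
    vals["irregularity_b"] = irregularity_b(d, seg)

    dl = smooth(sig.d_left, smoothing_window)
    dr = smooth(sig.d_right, smoothing_window)
    try:
        seg_l = segment_phases(dl, sig.frame_rate_hz, apex_frac=apex_frac, onset_frac=onset_frac)
        seg_r = segment_phases(dr, sig.frame_rate_hz, apex_frac=apex_frac, onset_frac=onset_frac)
        vals.update(symmetry(dl, dr, seg_l, seg_r, window=symmetry_window))
    except NoSmileError:
        vals.update(
            symmetry_a=math.nan, symmetry_b=math.nan, symmetry_c=math.nan, symmetry_d=math.nan
        )
    return SmileFeatures(**vals), seg
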