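"""Onset / apex / offset segmentation of a smile displacement signal.

The segmentation follows a five-step peak/valley scheme:

1. smooth D(t) with a centred moving average (window 3);
2. find all local maxima (peaks) and minima (valleys) of the smoothed signal,
   including the global maximum D_max;
3. the apex phase spans the region between the first and the last peak whose
   displacement exceeds 70% of D_max (a single qualifying peak gives a
   one-frame apex);
4. the onset frame is the valley nearest the apex, before it, whose
   displacement is below 20% of D_max; if no valley qualifies, the
   lowest-displacement frame before the apex;
5. the offset frame is defined symmetrically after the apex.

Frames are partitioned as onset = [onset_frame, apex_start), apex =
[apex_start, apex_end], offset = (apex_end, offset_frame], which guarantees
F(onset) + F(apex) + F(offset) = F(smile).

Plateaus (runs of exactly equal consecutive values, as produced by e.g. a
flat apex) are treated as a single extremum.  Its reported index is the run's
first frame, but phase boundaries respect the full run: a flat apex plateau
yields an apex phase spanning the whole plateau, not one frame.  Signal
endpooints are eligible as valleys (an episode may begin or end at rest) but
never as peaks: a signal still rising at the end has no complete apex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class NoSmileError(ValueError):
    """The signal contains no detectable smile (flat, or no qualifying peak)."""


@dataclass
class ExtremaSet:
    """Local extrema of a signal, with plateau runs collapsed.

    ``peaks`` / ``valleys`` hold the run-start indices (the conventional
    single-index view); ``peak_runs`` / ``valley_runs`` hold the full
    ``(start, end)`` inclusive extents needed for phase boundaries.
    """

    peaks: np.ndarray
    valleys: np.ndarray
    peak_runs: list[tuple[int, int]]
    valley_runs: list[tuple[int, int]]


def smooth(d: np.ndarray, window: int = 3) -> np.ndarray:
    """Centred moving average; endpoints use a shrunken (one-sided) window."""
    d = np.asarray(d, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    if window > len(d):
        raise ValueError(f"window {window} longer than signal ({len(d)} frames)")
    if window == 1:
        return d.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(d)])
    n = len(d)
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def _runs(d: np.ndarray, tol: float) -> list[tuple[int, int, float]]:
    """Compress consecutive near-equal values into (start, end, value) runs.

    Values within ``tol`` of the run's first sample join the run, so a
    nominally flat plateau stays one run despite last-ulp rounding in the
    distance arithmetic upstream.
    """
    runs = []
    start = 0
    for i in range(1, len(d)):
        if abs(d[i] - d[start]) > tol:
            runs.append((start, i - 1, d[start]))
            start = i
    runs.append((start, len(d) - 1, d[start]))
    return runs


def find_extrema(d: np.ndarray, rtol: float = 1e-9) -> ExtremaSet:
    """Local maxima and minima of ``d``, plateau runs collapsed.

    A run is a peak when both neighbouring runs are lower, a valley when both
    are higher.  The first and last runs are valleys when their single
    neighbour is higher.  Peaks and valleys alternate by construction.
    Samples closer than ``rtol`` times the signal's maximum magnitude are
    treated as equal (plateau members).
    """
    d = np.asarray(d, dtype=float)
    if len(d) < 3:
        raise ValueError("need at least 3 samples to locate extrema")
    tol = rtol * float(np.max(np.abs(d))) if len(d) else 0.0
    runs = _runs(d, tol)
    peaks: list[int] = []
    valleys: list[int] = []
    peak_runs: list[tuple[int, int]] = []
    valley_runs: list[tuple[int, int]] = []
    for k, (start, end, value) in enumerate(runs):
        left_higher = k > 0 and runs[k - 1][2] > value
        right_higher = k < len(runs) - 1 and runs[k + 1][2] > value
        left_lower = k > 0 and runs[k - 1][2] < value
        right_lower = k < len(runs) - 1 and runs[k + 1][2] < value
        if k == 0:
            if right_higher:
                valleys.append(start)
                valley_runs.append((start, end))
        elif k == len(runs) - 1:
            if left_higher:
                valleys.append(start)
                valley_runs.append((start, end))
        elif left_lower and right_lower:
            peaks.append(start)
            peak_runs.append((start, end))
        elif left_higher and right_higher:
            valleys.append(start)
            valley_runs.append((start, end))
    return ExtremaSet(
        peaks=np.asarray(peaks, dtype=int),
        valleys=np.asarray(valleys, dtype=int),
        peak_runs=peak_runs,
        valley_runs=valley_runs,
    )


@dataclass
class PhaseSegmentation:
    """Frame boundaries of one segmented smile, plus its peak displacement.

    All indices refer to the (smoothed) displacement signal the segmentation
    was computed from.
    """

    onset_frame: int
    apex_start: int
    apex_end: int
    offset_frame: int
    d_max: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if not (self.onset_frame <= self.apex_start <= self.apex_end <= self.offset_frame):
            raise ValueError(
                "phase boundaries out of order: "
                f"{self.onset_frame}, {self.apex_start}, {self.apex_end}, {self.offset_frame}"
            )

    # frame counts under the partition [onset, apex_start) [apex] (apex_end, offset]
    @property
    def n_onset(self) -> int:
        return self.apex_start - self.onset_frame

    @property
    def n_apex(self) -> int:
        return self.apex_end - self.apex_start + 1

    @property
    def n_offset(self) -> int:
        return self.offset_frame - self.apex_end

    @property
    def n_total(self) -> int:
        return self.offset_frame - self.onset_frame + 1

    def apex_slice(self) -> slice:
        return slice(self.apex_start, self.apex_end + 1)

    def onset_slice(self) -> slice:
        return slice(self.onset_frame, self.apex_start)

    def offset_slice(self) -> slice:
        return slice(self.apex_end + 1, self.offset_frame + 1)

    def smile_slice(self) -> slice:
        return slice(self.onset_frame, self.offset_frame + 1)


def segment_phases(
    d: np.ndarray,
    frame_rate_hz: float,
    apex_frac: float = 0.7,
    onset_frac: float = 0.2,
) -> PhaseSegmentation:
    """Segment a *smoothed* displacement signal into onset/apex/offset.

    ``apex_frac`` and ``onset_frac`` are the fractions of D_max defining
    apex-bounding peaks and onset/offset valleys (defaults 0.7 and 0.2).
    """
    d = np.asarray(d, dtype=float)
    d_max = float(np.max(d)) if len(d) else 0.0
    if d_max <= 0.0:
        raise NoSmileError("flat or non-positive signal: no smile to segment")
    ext = find_extrema(d)
    qualifying = [
        (start, end) for (start, end) in ext.peak_runs if d[start] > apex_frac * d_max
    ]
    if not qualifying:
        raise NoSmileError(
            f"no interior peak above {apex_frac:.0%} of the maximum displacement"
        )
    apex_start = qualifying[0][0]
    apex_end = qualifying[-1][1]

    # onset: qualifying valley nearest the apex (compare by the valley-run edge
    # facing the apex), else the lowest frame before the apex
    before = [
        (start, end)
        for (start, end) in ext.valley_runs
        if end < apex_start and d[start] < onset_frac * d_max
    ]
    if before:
        onset_frame = max(end for (_, end) in before)
    else:
        seg = d[:apex_start]
        # ties broken toward the apex
        onset_frame = int(len(seg) - 1 - np.argmin(seg[::-1]))

    after = [
        (start, end)
        for (start, end) in ext.valley_runs
        if start > apex_end and d[start] < onset_frac * d_max
    ]
    if after:
        offset_frame = min(start for (start, _) in after)
    else:
        tail = d[apex_end + 1 :]
        if len(tail) == 0:
            raise NoSmileError("apex extends to the final frame; no offset phase")
        offset_frame = apex_end + 1 + int(np.argmin(tail))

    return PhaseSegmentation(
        onset_frame=int(onset_frame),
        apex_start=int(apex_start),
        apex_end=int(apex_end),
        offset_frame=int(offset_frame),
        d_max=d_max,
        frame_rate_hz=frame_rate_hz,
    )
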