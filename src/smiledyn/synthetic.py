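"""Synthetic smile episodes with known ground truth.

The generator emulates the structure of the UvA-NEMO Smile Database — one
single smile per episode, 50 frames/s, neutral or near-neutral start and end,
roughly 4-second segments — without any real video: a 68-point neutral face
template whose two lip corners travel along fixed lateral/upward directions
following a rise / plateau / fall intensity trajectory, optionally under
sinusoidal rigid head motion and i.i.d. landmark jitter.

The intensity trajectory uses C1 smoothstep ramps (linear ramps would create
degenerate extrema at the phase joints).  The apex plateau carries a
Gaussian-smoothed "wobble" whose sample SD over the plateau is standardized
to the requested value, so the apex-SD irregularity feature has an exact
per-episode ground truth.  The right corner can lag the left by a signed
number of frames, scale by an amplitude ratio, and share only part of its
wobble with the left side; the shared-wobble fraction is calibrated in closed
form so the expected left/right Pearson correlation of a cohort hits a
requested target.

Cohort sampling draws per-subject trajectory parameters from truncated
normal distributions whose *post-truncation* mean and SD equal the
condition-level values observed for spontaneous ("genuine") and deliberate
("posed") enjoyment smiles; truncation bounds are physical minima
(durations at least 0.1 s, positive amplitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter1d

from .landmark_io import (
    ANCHOR_NOSTRIL,
    LEFT_LIP_CORNER,
    N_LANDMARKS,
    RIGHT_LIP_CORNER,
    HeadPose,
    LandmarkSequence,
)
from .pose_correction import apply_rotation

# ---------------------------------------------------------------------------
# condition-level population parameters (3D world units, mm; 50 fps).
# Each (mean, sd) pair is the target moment of the *truncated* sampling
# distribution for that per-subject parameter.


@dataclass(frozen=True)
class ConditionParams:
    """Population-level trajectory parameters for one smile condition."""

    onset_s: tuple[float, float]
    apex_s: tuple[float, float]
    offset_s: tuple[float, float]
    amplitude: tuple[float, float]
    residual_offset: tuple[float, float]
    apex_wobble_sd: tuple[float, float]
    lag_frames: tuple[float, float]       # signed right-minus-left onset lag
    symmetry_a_target: float              # expected left/right Pearson r
    amp_ratio_sd: float = 0.10            # right/left amplitude ratio spread


#: Spontaneous enjoyment smiles: long, with a marked residual "trace of a
#: smile", an unsteady apex, and larger left/right onset lags.
GENUINE = ConditionParams(
    onset_s=(0.93, 0.55),
    apex_s=(2.97, 1.55),
    offset_s=(1.10, 0.89),
    amplitude=(12.19, 3.43),
    residual_offset=(3.04, 1.58),
    apex_wobble_sd=(0.89, 0.48),
    lag_frames=(-1.28, 5.93),
    symmetry_a_target=0.92,
)

#: Deliberate smiles: brief, slightly wider, steadier at apex, more tightly
#: synchronized between the two sides.
POSED = ConditionParams(
    onset_s=(0.57, 0.24),
    apex_s=(1.84, 0.74),
    offset_s=(0.68, 0.34),
    amplitude=(12.97, 3.05),
    residual_offset=(2.62, 1.22),
    apex_wobble_sd=(0.66, 0.38),
    lag_frames=(-0.49, 3.85),
    symmetry_a_target=0.96,
)

CONDITIONS = {"genuine": GENUINE, "posed": POSED}

MIN_DURATION_S = 0.1


# ---------------------------------------------------------------------------
# truncated normal with matched post-truncation moments

def _trunc_ratio(alpha: float) -> float:
    # sd / (mean - lower) of a standard normal truncated at alpha, as a
    # function of the standardized truncation point; increasing from 0 to 1
    lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
    delta = lam * (lam - alpha)
    return math.sqrt(max(1.0 - delta, 0.0)) / (lam - alpha)


def truncated_normal(
    mean: float, sd: float, lower: float, rng: np.random.Generator, size: int | None = None
):
    """Sample a left-truncated normal whose truncated mean/SD are as given.

    The underlying (pre-truncation) location and scale are solved so that the
    distribution *after* truncation at ``lower`` has the requested moments;
    naive truncation of N(mean, sd) would inflate the mean whenever the bound
    is within a couple of SDs of it.  Requires sd < mean - lower (the
    truncated-normal family cannot exceed the exponential limit sd == mean -
    lower); degenerate sd <= 0 returns the constant mean.
    """
    if sd <= 0:
        out = np.full(size if size is not None else 1, float(max(mean, lower)))
        return out if size is not None else float(out[0])
    ratio = sd / (mean - lower)
    if not 0 < ratio < 0.995:
        raise ValueError(
            f"cannot match moments: sd/(mean-lower)={ratio:.3f} must be in (0, 1)"
        )
    alpha = optimize.brentq(lambda a: _trunc_ratio(a) - ratio, -12.0, 12.0, xtol=1e-12)
    lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
    delta = lam * (lam - alpha)
    sigma = sd / math.sqrt(1.0 - delta)
    mu = lower - alpha * sigma
    draws = stats.truncnorm.rvs(
        a=(lower - mu) / sigma, b=np.inf, loc=mu, scale=sigma,
        size=size if size is not None else 1, random_state=rng,
    )
    return draws if size is not None else float(draws[0])


# ---------------------------------------------------------------------------
# episode specification and ground truth


@dataclass
class SmileSpec:
    """Generative parameters for one synthetic smile episode."""

    onset_s: float = 0.93
    apex_s: float = 2.97
    offset_s: float = 1.10
    amplitude: float = 12.0           # mm of lip-corner travel at apex
    residual_offset: float = 0.0      # mm remaining where the smile ends
    apex_wobble_sd: float = 0.0       # SD of plateau fluctuation, mm
    peak_count_extra: int = 0         # extra prominent bumps on the plateau
    right_lag_frames: float = 0.0     # signed; positive = right starts later
    right_amp_ratio: float = 1.0
    lr_noise_corr: float = 1.0        # shared fraction of the two sides' wobble
    noise_sd: float = 0.0             # i.i.d. landmark coordinate jitter, mm
    frame_rate_hz: float = 50.0
    head_pose_amplitude: float = 0.0  # rad; 0 disables rigid head motion
    lead_in_s: float = 0.3            # neutral frames before the onset
    lead_out_s: float = 0.12          # frames held at the residual after offset
    wobble_smooth_frames: float = 3.0
    bump_amplitude_frac: float = 0.15  # bump height as a fraction of amplitude

    def __post_init__(self) -> None:
        for name in ("onset_s", "apex_s", "offset_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (self.amplitude > self.residual_offset >= 0):
            raise ValueError("need amplitude > residual_offset >= 0")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if not 0.0 <= self.lr_noise_corr <= 1.0:
            raise ValueError("lr_noise_corr must be in [0, 1]")


@dataclass
class GroundTruth:
    """Construction-time boundaries and parameter values for one episode."""

    rise_start: int
    plateau_start: int
    plateau_end: int
    fall_end: int
    onset_s: float
    apex_s: float
    offset_s: float
    amplitude: float
    residual_offset: float
    apex_wobble_sd: float
    lag_frames: int
    amp_ratio: float

    @property
    def total_s(self) -> float:
        return self.onset_s + self.apex_s + self.offset_s


# ---------------------------------------------------------------------------
# trajectory construction

def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _base_trajectory(spec: SmileSpec) -> tuple[np.ndarray, GroundTruth]:
    r = spec.frame_rate_hz
    n_lead = round(spec.lead_in_s * r)
    n_on = max(round(spec.onset_s * r), 1)
    n_apex = max(round(spec.apex_s * r), 1)
    n_off = max(round(spec.offset_s * r), 1)
    n_out = round(spec.lead_out_s * r)

    rise_start = n_lead
    plateau_start = rise_start + n_on
    plateau_end = plateau_start + n_apex - 1
    fall_end = plateau_end + n_off
    n = fall_end + n_out + 1

    t = np.arange(n)
    s = np.zeros(n)
    rise = (t >= rise_start) & (t < plateau_start)
    s[rise] = spec.amplitude * _smoothstep((t[rise] - rise_start) / n_on)
    s[(t >= plateau_start) & (t <= plateau_end)] = spec.amplitude
    fall = (t > plateau_end) & (t <= fall_end)
    s[fall] = spec.amplitude - (spec.amplitude - spec.residual_offset) * _smoothstep(
        (t[fall] - plateau_end) / n_off
    )
    s[t > fall_end] = spec.residual_offset

    gt = GroundTruth(
        rise_start=rise_start,
        plateau_start=plateau_start,
        plateau_end=plateau_end,
        fall_end=fall_end,
        onset_s=n_on / r,
        apex_s=n_apex / r,
        offset_s=n_off / r,
        amplitude=spec.amplitude,
        residual_offset=spec.residual_offset,
        apex_wobble_sd=spec.apex_wobble_sd,
        lag_frames=int(round(spec.right_lag_frames)),
        amp_ratio=spec.right_amp_ratio,
    )
    return s, gt


def _shift(x: np.ndarray, lag: int) -> np.ndarray:
    """Delay ``x`` by ``lag`` frames (negative lag advances), edge-padded."""
    idx = np.clip(np.arange(len(x)) - lag, 0, len(x) - 1)
    return x[idx]


def _smooth_noise_field(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = gaussian_filter1d(rng.standard_normal(n), sigma, mode="reflect")
    return w


def _plateau_wobble(
    field_: np.ndarray,
    start: int,
    end: int,
    target_sd: float,
    taper: int = 5,
    measure_window: int = 3,
) -> np.ndarray:
    """Window a noise field onto [start, end] and fix its sample SD there.

    The SD is standardized *as measured*: the scale is set so that the
    wobble seen through a centred ``measure_window`` moving average — the
    convention under which the apex-SD statistics this parameter is
    calibrated to were collected — has the target sample SD over the span.
    """
    from .segmentation import smooth

    n = len(field_)
    out = np.zeros(n)
    span = np.arange(max(start, 0), min(end, n - 1) + 1)
    if len(span) < 4 or target_sd <= 0:
        return out
    u = (span - span[0]) / max(len(span) - 1, 1)
    env = np.minimum(_smoothstep(u * len(span) / max(taper, 1)),
                     _smoothstep((1 - u) * len(span) / max(taper, 1)))
    w = field_[span] * env
    out[span] = w - w.mean()
    sd = out[span].std(ddof=1)
    if sd == 0.0:
        return out
    if measure_window > 1 and len(span) >= measure_window:
        sd = smooth(out, measure_window)[span].std(ddof=1)
    out *= target_sd / sd
    return out


def _bumps(
    rng: np.random.Generator, n: int, centers_lo: int, centers_hi: int,
    count: int, height: float, width_frames: int,
) -> np.ndarray:
    """Raised-cosine bumps for exercising the peak-prominence filter."""
    out = np.zeros(n)
    if count <= 0 or centers_hi <= centers_lo:
        return out
    for c in rng.integers(centers_lo, centers_hi + 1, size=count):
        lo = max(c - width_frames, 0)
        hi = min(c + width_frames, n - 1)
        tt = np.arange(lo, hi + 1)
        out[tt] += 0.5 * height * (1 + np.cos(np.pi * (tt - c) / width_frames))
    return out


# ---------------------------------------------------------------------------
# the face template


def neutral_face_3d() -> np.ndarray:
    """A stylized 68-point neutral face in mm (X right, Y down, Z depth).

    Only the relative geometry matters to the pipeline: the inner-nostril
    anchor sits near the origin and the two lip corners sit symmetrically
    below it.  Remaining points trace plausible jaw / brow / eye / nose /
    mouth contours so the file format is exercised realistically.
    """
    pts = np.zeros((N_LANDMARKS, 3))
    # jaw 0-16
    ang = np.linspace(np.pi, 2 * np.pi, 17)
    pts[0:17, 0] = 65 * np.cos(ang)
    pts[0:17, 1] = 20 - 75 * np.sin(ang)  # sin<=0 here -> chin at y≈95
    pts[0:17, 2] = 25 + 20 * np.abs(np.cos(ang))
    # brows 17-26
    for i, x in enumerate(np.linspace(-45, -10, 5)):
        pts[17 + i] = (x, -35.0, 8.0)
    for i, x in enumerate(np.linspace(10, 45, 5)):
        pts[22 + i] = (x, -35.0, 8.0)
    # nose bridge 27-30 and base 31-35 (index 33 = inner nostril anchor)
    pts[27:31] = np.column_stack(
        [np.zeros(4), np.linspace(-25, 5, 4), np.linspace(-5, -12, 4)]
    )
    for i, x in enumerate(np.linspace(-12, 12, 5)):
        pts[31 + i] = (x, 12.0, -4.0)
    pts[ANCHOR_NOSTRIL] = (0.0, 14.0, -6.0)
    # eyes 36-47
    for i, x in enumerate(np.linspace(-40, -18, 6)):
        pts[36 + i] = (x, -20.0 + 2.0 * math.sin(i), 2.0)
    for i, x in enumerate(np.linspace(18, 40, 6)):
        pts[42 + i] = (x, -20.0 + 2.0 * math.sin(i), 2.0)
    # outer lip 48-59 (48 right corner, 54 left corner), inner lip 60-67
    lip_ang = np.linspace(np.pi, 3 * np.pi, 12, endpoint=False)
    pts[48:60, 0] = 25 * np.cos(lip_ang)
    pts[48:60, 1] = 40 + 8 * np.sin(lip_ang)
    pts[48:60, 2] = 6.0
    pts[RIGHT_LIP_CORNER] = (-25.0, 40.0, 6.0)
    pts[LEFT_LIP_CORNER] = (25.0, 40.0, 6.0)
    inner_ang = np.linspace(np.pi, 3 * np.pi, 8, endpoint=False)
    pts[60:68, 0] = 18 * np.cos(inner_ang)
    pts[60:68, 1] = 40 + 4 * np.sin(inner_ang)
    pts[60:68, 2] = 5.0
    return pts


#: Unit directions of lip-corner travel (lateral + up + slightly back).
_DIR_RIGHT = np.array([-0.73, -0.62, 0.28])
_DIR_RIGHT /= np.linalg.norm(_DIR_RIGHT)
_DIR_LEFT = _DIR_RIGHT * np.array([-1.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# episode generation

def make_episode(
    spec: SmileSpec, seed: int | np.random.Generator
) -> tuple[LandmarkSequence, HeadPose, GroundTruth]:
    """Generate one synthetic 3D episode: landmarks, head pose, ground truth."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s, gt = _base_trajectory(spec)
    n = len(s)
    r = spec.frame_rate_hz

    lag = int(round(spec.right_lag_frames))
    max_lead = round(spec.lead_in_s * r)
    lag = int(np.clip(lag, -max_lead, max_lead))
    gt.lag_frames = lag

    # per-side wobble: shared + independent smooth fields, windowed onto each
    # side's own plateau, standardized so the *pooled* apex SD matches the spec
    c = spec.lr_noise_corr
    # effective inter-side wobble correlation: the shared field decorrelates
    # under this episode's lag by the smoothing kernel's autocorrelation
    eff = c * math.exp(-(lag**2) / (4.0 * spec.wobble_smooth_frames**2))
    side_sd = spec.apex_wobble_sd * math.sqrt(2.0 / (1.0 + eff)) if spec.apex_wobble_sd else 0.0
    w_shared = _smooth_noise_field(rng, n, spec.wobble_smooth_frames)
    w_l_ind = _smooth_noise_field(rng, n, spec.wobble_smooth_frames)
    w_r_ind = _smooth_noise_field(rng, n, spec.wobble_smooth_frames)
    mix_l = math.sqrt(c) * w_shared + math.sqrt(1.0 - c) * w_l_ind
    mix_r = math.sqrt(c) * _shift(w_shared, lag) + math.sqrt(1.0 - c) * w_r_ind
    wob_l = _plateau_wobble(mix_l, gt.plateau_start, gt.plateau_end, side_sd)
    wob_r = _plateau_wobble(
        mix_r, gt.plateau_start + lag, gt.plateau_end + lag, side_sd
    )

    bump = _bumps(
        rng, n, gt.plateau_start, gt.plateau_end,
        spec.peak_count_extra, spec.bump_amplitude_frac * spec.amplitude,
        width_frames=max(round(0.15 * r), 3),
    )

    s_left = np.maximum(s + wob_l + bump, 0.0)
    s_right = np.maximum(_shift(s, lag) + wob_r + _shift(bump, lag), 0.0) * spec.right_amp_ratio

    face = neutral_face_3d()
    coords = np.tile(face, (n, 1, 1))
    coords[:, LEFT_LIP_CORNER, :] += s_left[:, None] * _DIR_LEFT
    coords[:, RIGHT_LIP_CORNER, :] += s_right[:, None] * _DIR_RIGHT

    t_sec = np.arange(n) / r
    if spec.head_pose_amplitude > 0:
        freqs = np.array([0.23, 0.31, 0.17])
        phases = rng.uniform(0, 2 * np.pi, size=3)
        angles = spec.head_pose_amplitude * np.sin(
            2 * np.pi * freqs[None, :] * t_sec[:, None] + phases[None, :]
        )
        pose = HeadPose(pitch=angles[:, 0], yaw=angles[:, 1], roll=angles[:, 2])
        seq = apply_rotation(LandmarkSequence(coords, r), pose)
        coords = seq.coords
        # rigid translation drift on top of the rotation; anchoring removes it
        drift = 4.0 * np.sin(2 * np.pi * 0.2 * t_sec[:, None] + rng.uniform(0, 2 * np.pi, 3))
        coords = coords + drift[:, None, :]
    else:
        pose = HeadPose(np.zeros(n), np.zeros(n), np.zeros(n))

    if spec.noise_sd > 0:
        coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)

    return LandmarkSequence(coords, r), pose, gt


# ---------------------------------------------------------------------------
# cohort-level calibration and sampling

def _mean_lag_kernel_corr(lag_mu: float, lag_sd: float, kernel_sigma: float) -> float:
    # E[exp(-lag^2 / (4 sigma_k^2))] for lag ~ N(mu, sd): how much of the
    # shared wobble correlation survives a random inter-side lag
    a = 1.0 / (4.0 * kernel_sigma**2)
    denom = 1.0 + 2.0 * a * lag_sd**2
    return math.exp(-a * lag_mu**2 / denom) / math.sqrt(denom)


def _draw_trajectory_params(
    params: ConditionParams, rng: np.random.Generator
) -> tuple[float, float, float, float, float, float, float]:
    """One subject's trajectory parameters (shared by cohort sampling and the
    symmetry calibration quadrature so both see the same distribution)."""
    onset = truncated_normal(*params.onset_s, MIN_DURATION_S, rng)
    apex = truncated_normal(*params.apex_s, MIN_DURATION_S, rng)
    offset = truncated_normal(*params.offset_s, MIN_DURATION_S, rng)
    amplitude = truncated_normal(*params.amplitude, 1.0, rng)
    residual = min(truncated_normal(*params.residual_offset, 0.0, rng), 0.8 * amplitude)
    wobble = truncated_normal(*params.apex_wobble_sd, 0.0, rng)
    lag = rng.normal(*params.lag_frames)
    return onset, apex, offset, amplitude, residual, wobble, lag


def calibrate_shared_wobble(
    params: ConditionParams,
    noise_frac: float = 0.01,
    frame_rate_hz: float = 50.0,
    wobble_smooth_frames: float = 3.0,
    n_quadrature: int = 256,
) -> float:
    """Shared-wobble fraction c giving the condition's target left/right r.

    Per episode, the expected Pearson correlation over the smile span
    decomposes (to first order) as

        r = (V_s - lag^2 M / 2 + c rho(lag) f sigma_side^2)
            / (V_s + f sigma_side^2 + v_noise)

    where V_s is the variance of the clean trajectory over the span, M its
    mean squared frame-to-frame slope (the lag term is the classic
    misalignment penalty), f the apex fraction of the span, sigma_side the
    per-side wobble SD (which itself depends on c through the pooled-SD
    normalization), rho(lag) the wobble-kernel autocorrelation at the lag,
    and v_noise the landmark-jitter contribution after smoothing.

    Because short-duration episodes have much steeper ramps, the expectation
    of this ratio over the cohort's parameter distribution differs
    substantially from the ratio at the mean parameters, so the calibration
    averages the per-episode expression over a fixed deterministic parameter
    quadrature drawn from the same distributions as the cohort, then solves
    the scalar equation mean_i r_i(c) = target for c in [0, 1].
    """
    rng = np.random.default_rng(20180221)  # internal quadrature stream, fixed
    r_target = params.symmetry_a_target
    draws = []
    for _ in range(n_quadrature):
        onset, apex, offset, amplitude, residual, wobble, lag = _draw_trajectory_params(
            params, rng
        )
        spec = SmileSpec(
            onset_s=onset, apex_s=apex, offset_s=offset, amplitude=amplitude,
            residual_offset=residual, frame_rate_hz=frame_rate_hz,
        )
        s, gt = _base_trajectory(spec)
        span = s[gt.rise_start : gt.fall_end + 1]
        v_s = float(np.var(span))
        m_slope = float(np.mean(np.diff(span) ** 2))
        f_apex = (gt.plateau_end - gt.plateau_start + 1) / len(span)
        rho = math.exp(-(lag**2) / (4.0 * wobble_smooth_frames**2))
        v_n = 2.0 * (noise_frac * amplitude) ** 2 / 3.0
        c_sig = v_s - 0.5 * lag**2 * m_slope
        draws.append((c_sig, v_s, f_apex, wobble**2, rho, v_n))

    def mean_r(c: float) -> float:
        acc = 0.0
        for c_sig, v_s, f_apex, w2, rho, v_n in draws:
            eff = c * rho
            side2 = 2.0 * w2 / (1.0 + eff)
            num = c_sig + eff * f_apex * side2
            den = v_s + f_apex * side2 + v_n
            acc += max(min(num / den, 1.0), -1.0)
        return acc / len(draws)

    if mean_r(1.0) <= r_target:
        return 1.0
    if mean_r(0.0) >= r_target:
        return 0.0
    return float(optimize.brentq(lambda c: mean_r(c) - r_target, 0.0, 1.0, xtol=1e-6))


@dataclass
class CohortSample:
    """Per-subject specs for one condition, with lazily generated episodes."""

    condition: str
    subjects: list[str]
    specs: list[SmileSpec]
    episode_seeds: list[list[int]]

    def episodes(self):
        """Yield (subject, condition, LandmarkSequence, HeadPose, GroundTruth)."""
        for subject, spec, seeds in zip(self.subjects, self.specs, self.episode_seeds):
            for s in seeds:
                seq, pose, gt = make_episode(spec, s)
                yield subject, self.condition, seq, pose, gt


def sample_cohort(
    condition: str,
    n_subjects: int,
    episodes_per_subject: int = 1,
    seed: int | np.random.Generator = 0,
    noise_frac: float = 0.01,
    head_pose_amplitude: float = 0.05,
    frame_rate_hz: float = 50.0,
    subject_prefix: str = "S",
) -> CohortSample:
    """Draw per-subject episode specs for one condition.

    Durations, amplitude, residual and wobble are truncated normals with the
    condition's post-truncation moments; the right-corner onset lag is a
    plain normal (it is signed); landmark noise is ``noise_frac`` of each
    subject's amplitude.  Subject identity fixes the spec; multiple episodes
    per subject share it and differ only in the noise realization.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {sorted(CONDITIONS)}")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = CONDITIONS[condition]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c_shared = calibrate_shared_wobble(params, noise_frac, frame_rate_hz)

    subjects, specs, ep_seeds = [], [], []
    for i in range(n_subjects):
        onset, apex, offset, amplitude, residual, wobble, lag = _draw_trajectory_params(
            params, rng
        )
        ratio = float(np.clip(rng.normal(1.0, params.amp_ratio_sd), 0.7, 1.3))
        specs.append(
            SmileSpec(
                onset_s=onset,
                apex_s=apex,
                offset_s=offset,
                amplitude=amplitude,
                residual_offset=residual,
                apex_wobble_sd=wobble,
                right_lag_frames=lag,
                right_amp_ratio=ratio,
                lr_noise_corr=c_shared,
                noise_sd=noise_frac * amplitude,
                frame_rate_hz=frame_rate_hz,
                head_pose_amplitude=head_pose_amplitude,
            )
        )
        subjects.append(f"{subject_prefix}{i:04d}")
        ep_seeds.append([int(x) for x in rng.integers(0, 2**31 - 1, size=episodes_per_subject)])
    return CohortSample(condition, subjects, specs, ep_seeds)
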