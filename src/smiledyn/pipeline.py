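"""End-to-end orchestration: read -> correct -> displace -> segment ->
featurize -> QC -> cohort statistics, with reproducibility metadata.

Everything here is deterministic given the configuration and the inputs; a
run log records the package version, a hash of the configuration, and the
exclusion counts by reason so a features table can always be traced back to
the settings that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import pandas as pd

from . import __version__
from .cohort_stats import CohortResult, QCResult, aggregate, cohort_analysis, qc_filter
from .displacement import METHODS, compute_displacement
from .features import FEATURE_NAMES, PhaseSegmentation, SmileFeatures, extract_features
from .landmark_io import ANCHOR_NOSTRIL, HeadPose, LandmarkSequence, interpolate_invalid, read_openface_csv
from .pose_correction import correct
from .segmentation import NoSmileError, smooth

logger = logging.getLogger("smiledyn")


@dataclass
class RunConfig:
    """All tunables of one pipeline run.  Defaults reproduce the reference
    analysis: 3D mode, from-rest displacement, window-3 smoothing, 70%/20%
    apex/onset thresholds, 10% peak prominence, 0.2 s minimum offset."""

    mode: str = "3d"
    method: str = "from_rest"
    smoothing_window: int = 3
    apex_frac: float = 0.7
    onset_frac: float = 0.2
    prominence_frac: float = 0.1
    qc_min_offset_s: float = 0.2
    alpha: float = 0.01
    anchor: int = ANCHOR_NOSTRIL
    frame_rate_hz: float = 50.0
    max_invalid_gap: int = 5
    symmetry_window: str = "union"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("2d", "3d"):
            raise ValueError("mode must be '2d' or '3d'")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd")
        for name in ("apex_frac", "onset_frac", "prominence_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class RunLog:
    version: str
    config_hash: str
    n_episodes: int = 0
    n_failed: int = 0
    exclusions: dict = field(default_factory=dict)


def process_episode(
    seq: LandmarkSequence, pose: HeadPose | None, config: RunConfig
) -> tuple[SmileFeatures, PhaseSegmentation, QCResult]:
    """Run one episode through correction, displacement, features and QC."""
    seq = interpolate_invalid(seq, max_gap=config.max_invalid_gap)
    seq = correct(seq, pose, anchor=config.anchor)
    sig = compute_displacement(seq, method=config.method)
    feats, seg = extract_features(
        sig,
        smoothing_window=config.smoothing_window,
        apex_frac=config.apex_frac,
        onset_frac=config.onset_frac,
        prominence_frac=config.prominence_frac,
        symmetry_window=config.symmetry_window,
    )
    d = smooth(sig.d, config.smoothing_window)
    qc = qc_filter(d, seg, min_offset_s=config.qc_min_offset_s)
    return feats, seg, qc


def episode_record(
    subject: str, condition: str, feats: SmileFeatures, qc: QCResult
) -> dict:
    rec = {"subject": subject, "condition": condition,
           "qc_keep": qc.keep, "qc_reason": qc.reason}
    rec.update(feats.as_dict())
    return rec


@dataclass
class PipelineResult:
    features: pd.DataFrame
    cohort: CohortResult | None
    log: RunLog


def synthetic_cohort_features(
    condition: str,
    n_subjects: int,
    seed,
    config: RunConfig | None = None,
    episodes_per_subject: int = 1,
    noise_frac: float = 0.01,
) -> pd.DataFrame:
    """Generate one synthetic cohort and featurize every episode.

    Convenience for calibration and recovery studies: draws the cohort with
    :func:`smiledyn.synthetic.sample_cohort` and runs each episode through
    :func:`process_episode`, returning the per-episode feature table.
    """
    from .synthetic import sample_cohort

    config = config or RunConfig()
    cohort = sample_cohort(
        condition, n_subjects, episodes_per_subject, seed=seed, noise_frac=noise_frac,
        frame_rate_hz=config.frame_rate_hz,
    )
    episodes = ((s, c, seq, pose) for s, c, seq, pose, _gt in cohort.episodes())
    return run_pipeline(config, episodes, run_stats=False).features


def run_pipeline(config: RunConfig, episodes, run_stats: bool = True) -> PipelineResult:
    """Process a list of episodes and (optionally) run the cohort statistics.

    ``episodes`` yields either ``(subject, condition, csv_path)`` triples or
    in-memory ``(subject, condition, LandmarkSequence, HeadPose)`` tuples.
    Unreadable or unsegmentable episodes are logged and skipped; the run
    fails only if nothing could be processed.
    """
    log = RunLog(version=__version__, config_hash=config.config_hash())
    records = []
    for item in episodes:
        subject, condition = item[0], item[1]
        try:
            if len(item) == 3:
                seq, pose = read_openface_csv(
                    item[2], mode=config.mode, frame_rate_hz=config.frame_rate_hz
                )
            else:
                seq, pose = item[2], item[3]
            feats, seg, qc = process_episode(seq, pose, config)
        except (NoSmileError, ValueError, OSError) as exc:
            log.n_failed += 1
            logger.warning("skipping episode %s/%s: %s", subject, condition, exc)
            continue
        log.n_episodes += 1
        if not qc.keep:
            log.exclusions[qc.reason] = log.exclusions.get(qc.reason, 0) + 1
        records.append(episode_record(subject, condition, feats, qc))
    if not records:
        raise RuntimeError("no episode could be processed")
    features = pd.DataFrame(records, columns=["subject", "condition", "qc_keep", "qc_reason", *FEATURE_NAMES])

    cohort = None
    if run_stats:
        try:
            paired = aggregate(features)
            # the joint test needs complete feature vectors
            cohort = cohort_analysis(paired.dropna())
        except ValueError as exc:
            logger.warning("cohort statistics skipped: %s", exc)
    logger.info(
        "pipeline %s: %d episodes (%d failed), exclusions %s",
        log.config_hash, log.n_episodes, log.n_failed, log.exclusions,
    )
    return PipelineResult(features, cohort, log)
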