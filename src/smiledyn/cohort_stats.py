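"""Episode QC, subject-level aggregation, and paired cohort statistics.

Episodes are screened with two rules before any statistics: an episode is
excluded when (1) its mean offset-phase displacement exceeds its mean
apex-phase displacement (a shape that usually signals a complex expression or
a mis-segmentation), or (2) its offset phase is shorter than 0.2 s.  Retained
episodes are averaged per subject and condition, and subjects lacking either
condition are dropped, yielding a strictly paired cohort.

The condition contrast is a one-way repeated-measures design: per feature, a
paired t test reported as F(1, n-1) = t^2 with partial eta^2 = F/(F + df_err);
jointly, a one-sample Hotelling T^2 on the per-subject condition-difference
vectors, reported as F(p, n-p) with partial eta^2 = T^2/(T^2 + n - 1).

The 17 features contain two exact linear dependencies (the three phase ratios
sum to one, and the total duration is the sum of the three phase durations),
so the multivariate test runs on a 15-variable set that drops total_duration
and apex_ratio; with n paired subjects its error df is n - 15.

Significance is read against a strict alpha = 0.01, but the emphasis is on
effect sizes: with hundreds of paired subjects nearly any difference reaches
conventional significance.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES
from .segmentation import PhaseSegmentation

#: Multivariate DV set: the 17 features minus the two linearly dependent ones.
MANOVA_FEATURES = tuple(
    name for name in FEATURE_NAMES if name not in ("total_duration", "apex_ratio")
)

ALPHA = 0.01


@dataclass
class QCResult:
    keep: bool
    reason: str = ""


def qc_filter(d: np.ndarray, seg: PhaseSegmentation, min_offset_s: float = 0.2) -> QCResult:
    """Apply the two exclusion rules to one segmented episode."""
    if seg.n_offset / seg.frame_rate_hz < min_offset_s:
        return QCResult(False, "offset<0.2s")
    offset_mean = float(np.mean(d[seg.offset_slice()])) if seg.n_offset else math.inf
    apex_mean = float(np.mean(d[seg.apex_slice()]))
    if offset_mean > apex_mean:
        return QCResult(False, "offset>apex")
    return QCResult(True)


def aggregate(episodes: pd.DataFrame) -> pd.DataFrame:
    """Average QC-passed episodes to one feature vector per subject x condition.

    Expects columns ``subject``, ``condition``, optionally ``qc_keep``, plus
    the features.  Subjects observed in only one condition are dropped so the
    result is a paired cohort (one row per subject and condition).
    """
    df = episodes
    if "qc_keep" in df.columns:
        df = df[df["qc_keep"].astype(bool)]
    if len(df) == 0:
        raise ValueError("no episodes left after QC; cannot aggregate")
    feats = [c for c in FEATURE_NAMES if c in df.columns]
    agg = df.groupby(["subject", "condition"], as_index=False)[feats].mean()
    counts = agg.groupby("subject")["condition"].nunique()
    paired_subjects = counts[counts == 2].index
    agg = agg[agg["subject"].isin(paired_subjects)].reset_index(drop=True)
    if len(agg) == 0:
        raise ValueError("no subject has episodes in both conditions")
    return agg


def partial_eta_sq_univariate(F: float, df_error: int) -> float:
    """Partial eta^2 for a 1-df within-subject effect: F / (F + df_error)."""
    if F < 0:
        raise ValueError("F statistic cannot be negative")
    if df_error <= 0:
        raise ValueError("df_error must be positive")
    return F / (F + df_error)


@dataclass
class UnivariateResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    degenerate: bool = False


def paired_univariate(x_genuine: np.ndarray, x_posed: np.ndarray) -> UnivariateResult:
    """Paired t test reported in F form: F(1, n-1) = t^2, with partial eta^2.

    Zero-variance differences are a degenerate case: F is 0 (no difference at
    all) or infinite (a perfectly constant nonzero shift), flagged as such.
    """
    x_genuine = np.asarray(x_genuine, dtype=float)
    x_posed = np.asarray(x_posed, dtype=float)
    if x_genuine.shape != x_posed.shape or x_genuine.ndim != 1:
        raise ValueError("need two paired 1-d vectors")
    n = len(x_genuine)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x_genuine).all() and np.isfinite(x_posed).all()):
        raise ValueError("non-finite feature values; aggregate or impute first")
    diff = x_genuine - x_posed
    if np.std(diff, ddof=1) == 0.0:
        if np.all(diff == 0.0):
            return UnivariateResult(0.0, 1, n - 1, 1.0, 0.0, degenerate=True)
        return UnivariateResult(math.inf, 1, n - 1, 0.0, 1.0, degenerate=True)
    t, p = stats.ttest_rel(x_genuine, x_posed)
    F = float(t) ** 2
    return UnivariateResult(F, 1, n - 1, float(p), partial_eta_sq_univariate(F, n - 1))


@dataclass
class MultivariateResult:
    T2: float
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    n: int


def repeated_manova(differences: np.ndarray) -> MultivariateResult:
    """One-sample Hotelling T^2 on the n x p condition-difference matrix.

    T^2 = n m' S^-1 m with the sample covariance S; reported as
    F = T^2 (n - p) / (p (n - 1)) on (p, n - p) df, with
    partial eta^2 = T^2 / (T^2 + n - 1).  With p = 1 this reduces exactly to
    the paired t test.
    """
    X = np.asarray(differences, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects than variables (n={n}, p={p})")
    m = X.mean(axis=0)
    if np.allclose(X, 0.0):
        return MultivariateResult(0.0, 0.0, p, n - p, 1.0, 0.0, n)
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    try:
        solved = np.linalg.solve(S, m)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance among dependent variables; drop linearly "
            "dependent features (see MANOVA_FEATURES) and retry"
        ) from exc
    T2 = float(n * m @ solved)
    if T2 < 0:  # numerically indefinite covariance
        raise ValueError("covariance matrix is not positive definite")
    F = T2 * (n - p) / (p * (n - 1))
    pval = float(stats.f.sf(F, p, n - p))
    return MultivariateResult(T2, F, p, n - p, pval, T2 / (T2 + n - 1), n)


@dataclass
class CohortResult:
    """Per-feature descriptive and inferential statistics plus the joint test."""

    table: pd.DataFrame
    multivariate: MultivariateResult
    n_subjects: int
    alpha: float = ALPHA

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def cohort_analysis(
    paired: pd.DataFrame,
    conditions: tuple[str, str] = ("genuine", "posed"),
    manova_features: tuple[str, ...] = MANOVA_FEATURES,
) -> CohortResult:
    """Run the full paired analysis on an aggregated subject x condition table.

    Produces one row per feature (genuine M/SD, posed M/SD, F, p, partial
    eta^2) in the canonical feature order, plus the joint multivariate test on
    ``manova_features``.
    """
    a, b = conditions
    wide = paired.pivot(index="subject", columns="condition", values=list(FEATURE_NAMES))
    for cond in conditions:
        if cond not in paired["condition"].unique():
            raise ValueError(f"condition {cond!r} absent from cohort")
    wide = wide.dropna()
    n = len(wide)
    rows = []
    for name in FEATURE_NAMES:
        xa = wide[(name, a)].to_numpy()
        xb = wide[(name, b)].to_numpy()
        res = paired_univariate(xa, xb)
        rows.append(
            {
                "feature": name,
                f"{a}_mean": xa.mean(),
                f"{a}_sd": xa.std(ddof=1),
                f"{b}_mean": xb.mean(),
                f"{b}_sd": xb.std(ddof=1),
                "F": res.F,
                "p": res.p,
                "partial_eta_sq": res.partial_eta_sq,
            }
        )
    diffs = np.column_stack(
        [wide[(name, a)].to_numpy() - wide[(name, b)].to_numpy() for name in manova_features]
    )
    multi = repeated_manova(diffs)
    return CohortResult(pd.DataFrame(rows), multi, n_subjects=n)
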