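#!/usr/bin/env python
"""Repeat the cohort contrast in 2D (image-plane) mode.

The 2D pipeline sees the orthographic projection of the same synthetic
episodes (X, Y only) and applies anchoring but no rotation correction, so
residual head motion leaks into the displacement signal — the same asymmetry
the two landmark systems have on real video. Writes
results/cohort_stats_2d.csv and prints how the two modes compare on the
headline features.

Run from the repository root:  python analysis/04_2d_mode_comparison.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from smiledyn.cohort_stats import aggregate, cohort_analysis
from smiledyn.landmark_io import LandmarkSequence
from smiledyn.pipeline import RunConfig, run_pipeline
from smiledyn.synthetic import sample_cohort

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

N_SUBJECTS = 100
SEED = 2018  # same cohorts as 02_extract_features.py


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    children = np.random.SeedSequence(SEED).spawn(2)
    episodes = []
    for condition, child in zip(("genuine", "posed"), children):
        cohort = sample_cohort(condition, N_SUBJECTS, seed=np.random.default_rng(child))
        for subject, cond, seq, pose, _gt in cohort.episodes():
            flat = LandmarkSequence(seq.coords[:, :, :2], seq.frame_rate_hz, seq.valid)
            episodes.append((subject, cond, flat, pose))

    result = run_pipeline(RunConfig(mode="2d"), episodes)
    result.cohort.to_csv(RESULTS / "cohort_stats_2d.csv")

    m = result.cohort.multivariate
    print(f"2D mode, n = {result.cohort.n_subjects} paired subjects: "
          f"F({m.df1}, {m.df2}) = {m.F:.2f}, partial eta^2 = {m.partial_eta_sq:.3f}")

    stats_3d = pd.read_csv(RESULTS / "cohort_stats_3d.csv").set_index("feature")
    stats_2d = result.cohort.table.set_index("feature")
    print(f"{'feature':<22}{'eta2 3D':>9}{'eta2 2D':>9}")
    for feat in ("total_duration", "onset_speed", "offset_speed", "symmetry_a",
                 "symmetry_d", "irregularity_b"):
        print(f"{feat:<22}{stats_3d.loc[feat, 'partial_eta_sq']:>9.3f}"
              f"{stats_2d.loc[feat, 'partial_eta_sq']:>9.3f}")
    print("(uncorrected head motion mostly dilutes, but does not reverse, the contrasts)")


if __name__ == "__main__":
    main()
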