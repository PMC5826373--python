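import numpy as np
import pandas as pd
import pytest

from smiledyn.cohort_stats import (
    MANOVA_FEATURES,
    aggregate,
    cohort_analysis,
    paired_univariate,
    partial_eta_sq_univariate,
    qc_filter,
    repeated_manova,
)
from smiledyn.features import FEATURE_NAMES
from smiledyn.segmentation import PhaseSegmentation, segment_phases

from conftest import trapezoid


class TestQCFilter:
    def test_short_offset_excluded(self):
        # offset of 5 frames at 50 fps = 0.10 s
        seg = PhaseSegmentation(0, 50, 149, 154, 10.0, 50.0)
        res = qc_filter(trapezoid(), seg)
        assert not res.keep and res.reason == "offset<0.2s"

    def test_offset_stronger_than_apex_excluded(self):
        d = np.concatenate([np.zeros(1), np.full(10, 6.0), np.full(20, 8.0)])
        seg = PhaseSegmentation(0, 1, 10, 30, 8.0, 50.0)
        res = qc_filter(d, seg)
        assert not res.keep and res.reason == "offset>apex"

    def test_trapezoid_kept(self):
        seg = segment_phases(trapezoid(), 50.0)
        assert qc_filter(trapezoid(), seg).keep


class TestAggregate:
    @staticmethod
    def _table(rows):
        recs = []
        for subject, condition, value in rows:
            rec = {"subject": subject, "condition": condition, "qc_keep": True}
            rec.update({name: value for name in FEATURE_NAMES})
            recs.append(rec)
        return pd.DataFrame(recs)

    def test_unpaired_subject_dropped(self):
        df = self._table([("a", "genuine", 1.0), ("a", "genuine", 3.0),
                          ("b", "genuine", 2.0), ("b", "posed", 2.0)])
        agg = aggregate(df)
        assert set(agg["subject"]) == {"b"}

    def test_episode_mean(self):
        df = self._table([("a", "genuine", 1.0), ("a", "genuine", 3.0),
                          ("a", "posed", 5.0)])
        agg = aggregate(df)
        row = agg[(agg.subject == "a") & (agg.condition == "genuine")]
        assert row["onset_duration"].item() == pytest.approx(2.0)

    def test_fully_paired_cohort_size(self):
        rows = [(f"s{i}", c, float(i)) for i in range(5) for c in ("genuine", "posed")]
        agg = aggregate(self._table(rows))
        assert len(agg) == 10
        assert (agg.groupby("condition").size() == 5).all()

    def test_empty_after_qc_rejected(self):
        df = self._table([("a", "genuine", 1.0)])
        df["qc_keep"] = False
        with pytest.raises(ValueError):
            aggregate(df)


class TestPartialEtaSq:
    @pytest.mark.parametrize(
        "F, df, expected",
        [
            # published 1-df repeated-measures F statistics with 296 error df
            (130.375, 296, 0.306),
            (271.829, 296, 0.479),
            (60.481, 296, 0.170),
            (46.802, 296, 0.137),
            (8.343, 296, 0.027),
        ],
    )
    def test_closed_form_matches_printed_effect_sizes(self, F, df, expected):
        assert partial_eta_sq_univariate(F, df) == pytest.approx(expected, abs=5e-4)

    def test_zero_F(self):
        assert partial_eta_sq_univariate(0.0, 100) == 0.0

    def test_monotone_in_F_and_bounded(self):
        F = np.linspace(0, 500, 100)
        eta = np.array([partial_eta_sq_univariate(f, 296) for f in F])
        assert np.all(np.diff(eta) > 0)
        assert np.all((eta >= 0) & (eta < 1))


class TestPairedUnivariate:
    def test_identical_conditions(self):
        x = np.arange(10.0)
        res = paired_univariate(x, x)
        assert res.F == 0.0 and res.partial_eta_sq == 0.0 and res.p == 1.0

    def test_three_pair_hand_computation(self):
        # pairs (1,2) (2,2) (3,5): differences (-1, 0, -2), mean -1, sd 1
        # t = -1 / (1/sqrt(3)) = -sqrt(3), F = t^2 = 3
        res = paired_univariate(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 5.0]))
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert res.df2 == 2
        assert res.partial_eta_sq == pytest.approx(3.0 / 5.0)

    def test_power_at_large_shift(self, rng):
        hits = 0
        for _ in range(50):
            x = rng.normal(0, 1, 297)
            y = x + 1.0 + rng.normal(0, 1, 297)
            if paired_univariate(y, x).p < 0.01:
                hits += 1
        assert hits == 50  # delta = 1 sd at n = 297: essentially always detected

    def test_constant_nonzero_shift_degenerate(self):
        x = np.arange(5.0)
        res = paired_univariate(x + 2.0, x)
        assert res.degenerate and np.isinf(res.F)


class TestRepeatedManova:
    def test_zero_differences(self):
        res = repeated_manova(np.zeros((10, 3)) + 0.0)
        assert res.T2 == 0.0 and res.F == 0.0 and res.partial_eta_sq == 0.0

    def test_published_multivariate_effect_size(self):
        # F(15, 282) = 37.126 with n = 297 implies T^2 = F p (n-1)/(n-p)
        n, p, F = 297, 15, 37.126
        T2 = F * p * (n - 1) / (n - p)
        assert T2 / (T2 + n - 1) == pytest.approx(0.664, abs=5e-4)

    def test_p_equal_one_reduces_to_paired_t(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.3, 0.5, 40)
        uni = paired_univariate(y, x)
        multi = repeated_manova((y - x)[:, None])
        assert multi.F == pytest.approx(uni.F, abs=1e-9)
        assert multi.partial_eta_sq == pytest.approx(uni.partial_eta_sq, abs=1e-9)
        assert multi.p == pytest.approx(uni.p, abs=1e-9)

    def test_matches_independent_hotelling_implementation(self, rng):
        pingouin = pytest.importorskip("pingouin")
        X = rng.normal(0.2, 1.0, size=(60, 4))
        ours = repeated_manova(X)
        ref = pingouin.multivariate_ttest(X)
        assert ours.F == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert ours.df1 == int(ref["df1"].iloc[0])
        assert ours.df2 == int(ref["df2"].iloc[0])
        assert ours.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_singular_covariance_instructive_error(self, rng):
        x = rng.normal(size=30)
        X = np.column_stack([x, 2.0 * x])  # exactly collinear
        with pytest.raises(ValueError):
            repeated_manova(X)

    def test_more_variables_than_subjects_rejected(self, rng):
        with pytest.raises(ValueError):
            repeated_manova(rng.normal(size=(5, 6)))


class TestCohortAnalysis:
    @staticmethod
    def _paired_frame(rng, n=30, shift=0.5):
        rows = []
        for i in range(n):
            base = rng.normal(0, 1, 17)
            for cond, delta in (("genuine", shift), ("posed", 0.0)):
                rec = {"subject": f"s{i}", "condition": cond}
                vec = base + delta + rng.normal(0, 0.3, 17)
                rec.update(dict(zip(FEATURE_NAMES, vec)))
                rows.append(rec)
        return pd.DataFrame(rows)

    def test_table_layout_and_dfs(self, rng):
        res = cohort_analysis(self._paired_frame(rng))
        assert list(res.table["feature"]) == list(FEATURE_NAMES)
        assert set(res.table.columns) >= {"genuine_mean", "genuine_sd", "posed_mean",
                                          "posed_sd", "F", "p", "partial_eta_sq"}
        assert res.multivariate.df1 == len(MANOVA_FEATURES) == 15
        assert res.multivariate.df2 == res.n_subjects - 15

    def test_eta_bounds(self, rng):
        res = cohort_analysis(self._paired_frame(rng))
        eta = res.table["partial_eta_sq"].to_numpy()
        assert np.all((eta >= 0) & (eta <= 1))
        assert 0.0 <= res.multivariate.partial_eta_sq < 1.0


class TestTypeIError:
    def test_null_rejection_rate_near_alpha(self, rng):
        """Over 10,000 null replicates (n = 50 pairs), the paired test rejects
        at alpha = 0.01 between 0.5% and 2% of the time."""
        n_rep, n = 10_000, 50
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        rejections = 0
        for k in range(n_rep):
            if paired_univariate(x[k], y[k]).p <= 0.01:
                rejections += 1
        rate = rejections / n_rep
        assert 0.005 <= rate <= 0.02
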