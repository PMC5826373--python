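import numpy as np
import pytest

from smiledyn.displacement import DisplacementSignal
from smiledyn.features import (
    displacement_features,
    durations,
    extract_features,
    irregularity_a,
    irregularity_b,
    speeds,
    symmetry,
)
from smiledyn.segmentation import PhaseSegmentation, segment_phases, smooth

from conftest import trapezoid


def _trapezoid_seg():
    # exact construction boundaries of the canonical trapezoid at 50 fps
    return PhaseSegmentation(
        onset_frame=0, apex_start=50, apex_end=149, offset_frame=199,
        d_max=10.0, frame_rate_hz=50.0,
    )


class TestDurations:
    def test_trapezoid_durations_and_ratios(self):
        out = durations(_trapezoid_seg())
        assert out["onset_duration"] == pytest.approx(1.0)
        assert out["apex_duration"] == pytest.approx(2.0)
        assert out["offset_duration"] == pytest.approx(1.0)
        assert out["total_duration"] == pytest.approx(4.0)
        assert (out["onset_ratio"], out["apex_ratio"], out["offset_ratio"]) == (
            pytest.approx(0.25), pytest.approx(0.5), pytest.approx(0.25))

    def test_one_frame_apex(self):
        seg = PhaseSegmentation(0, 10, 10, 20, 5.0, 50.0)
        assert durations(seg)["apex_duration"] == pytest.approx(0.02)

    def test_ratios_sum_to_one_and_durations_add_up(self):
        out = durations(PhaseSegmentation(3, 17, 61, 88, 1.0, 50.0))
        assert out["onset_ratio"] + out["apex_ratio"] + out["offset_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert out["onset_duration"] + out["apex_duration"] + out["offset_duration"] == pytest.approx(
            out["total_duration"], abs=1e-9)


class TestDisplacementFeatures:
    def test_trapezoid(self):
        out = displacement_features(trapezoid(), _trapezoid_seg())
        assert out["max_displacement"] == pytest.approx(10.0)
        assert out["offset_displacement"] == pytest.approx(0.0)

    def test_truncated_fall_leaves_residual(self):
        d = trapezoid(residual=3.0)
        seg = segment_phases(d, 50.0)
        out = displacement_features(d, seg)
        assert out["offset_displacement"] == pytest.approx(3.0)

    def test_max_at_least_apex_mean(self, rng):
        d = trapezoid() + rng.normal(0, 0.1, 200)
        seg = _trapezoid_seg()
        out = displacement_features(d, seg)
        assert out["max_displacement"] >= np.mean(d[50:150])


class TestSpeeds:
    def test_linear_rise_speed(self):
        out = speeds(trapezoid(), _trapezoid_seg())
        assert out["onset_speed"] == pytest.approx(10.0)  # 10 units over 1.0 s

    def test_symmetric_fall_over_two_seconds(self):
        d = trapezoid(n_fall=100)
        seg = PhaseSegmentation(0, 50, 149, 249, 10.0, 50.0)
        assert speeds(d, seg)["offset_speed"] == pytest.approx(5.0)

    def test_constant_offset_adds_nothing(self):
        out1 = speeds(trapezoid(), _trapezoid_seg())
        out2 = speeds(trapezoid() + 5.0, _trapezoid_seg())
        assert out2["onset_speed"] == pytest.approx(out1["onset_speed"])
        assert out2["offset_speed"] == pytest.approx(out1["offset_speed"])

    def test_speed_scales_with_amplitude(self):
        out1 = speeds(trapezoid(), _trapezoid_seg())
        out2 = speeds(3.0 * trapezoid(), _trapezoid_seg())
        assert out2["onset_speed"] == pytest.approx(3.0 * out1["onset_speed"])

    def test_zero_length_phase_flagged(self):
        seg = PhaseSegmentation(5, 5, 10, 20, 1.0, 50.0)  # no onset frames
        assert np.isnan(speeds(trapezoid(), seg)["onset_speed"])


class TestIrregularityA:
    def test_trapezoid_single_peak(self):
        assert irregularity_a(trapezoid(), _trapezoid_seg()) == pytest.approx(0.25)

    def test_two_prominent_peaks_in_two_seconds(self):
        d = np.concatenate([
            np.linspace(0, 10, 26),
            np.linspace(10, 1, 25)[1:],
            np.linspace(1, 10, 26)[1:],
            np.linspace(10, 0, 26)[1:],
        ])
        assert len(d) == 100
        seg = segment_phases(d, 50.0)
        assert seg.n_total == 100
        assert irregularity_a(d, seg) == pytest.approx(1.0)  # 2 peaks / 2 s

    def test_tiny_ripple_filtered_out(self):
        d = trapezoid().astype(float)
        d[50:150] += 0.005 * 10.0 * np.sin(np.arange(100))  # 0.5% of d_max ripple
        seg = segment_phases(d, 50.0)
        assert irregularity_a(d, seg) == pytest.approx(1.0 / (seg.n_total / 50.0))

    def test_unimodal_rate_is_inverse_duration(self):
        d = np.concatenate([np.linspace(0, 8, 101), np.linspace(8, 0, 101)[1:]])
        seg = segment_phases(d, 50.0)
        assert irregularity_a(d, seg) == pytest.approx(1.0 / (seg.n_total / 50.0))


class TestIrregularityB:
    def test_constant_apex_is_zero(self):
        assert irregularity_b(trapezoid(), _trapezoid_seg()) == pytest.approx(0.0)

    def test_sample_sd_arithmetic(self):
        d = np.zeros(30)
        d[10:13] = [9.0, 10.0, 11.0]
        seg = PhaseSegmentation(0, 10, 12, 20, 11.0, 50.0)
        assert irregularity_b(d, seg) == pytest.approx(1.0)  # ddof=1

    def test_one_frame_apex_is_zero(self):
        seg = PhaseSegmentation(0, 10, 10, 20, 5.0, 50.0)
        assert irregularity_b(np.arange(30.0), seg) == 0.0

    def test_recovers_injected_wobble(self, rng):
        d = trapezoid(n_plateau=150)
        d[50:200] += rng.normal(0, 0.9, 150)
        seg = PhaseSegmentation(0, 50, 199, 249, 10.0, 50.0)
        assert irregularity_b(d, seg) == pytest.approx(0.9, rel=0.10)


class TestSymmetry:
    def test_identical_sides(self):
        d = trapezoid()
        seg = segment_phases(d, 50.0)
        out = symmetry(d, d, seg, seg)
        assert out["symmetry_a"] == pytest.approx(1.0)
        assert out["symmetry_b"] == pytest.approx(0.0)
        assert out["symmetry_c"] == 0.0 and out["symmetry_d"] == 0.0

    def test_scaled_side_keeps_perfect_correlation(self):
        d = trapezoid()
        seg_l = segment_phases(d, 50.0)
        seg_r = segment_phases(2.0 * d, 50.0)
        out = symmetry(d, 2.0 * d, seg_l, seg_r)
        assert out["symmetry_a"] == pytest.approx(1.0)
        assert out["symmetry_b"] > 0  # right apex is stronger

    def test_lagged_side_measured_in_frames(self):
        d_left = trapezoid()
        d_right = np.concatenate([np.zeros(5), d_left[:-5]])  # right starts later
        seg_l = segment_phases(d_left, 50.0)
        seg_r = segment_phases(d_right, 50.0)
        out = symmetry(d_left, d_right, seg_l, seg_r)
        assert out["symmetry_c"] == 5.0
        assert out["symmetry_d"] == 5.0

    def test_zero_variance_side_flagged(self):
        d = trapezoid()
        seg = segment_phases(d, 50.0)
        flat = np.full_like(d, 1.0)
        out = symmetry(flat, d, seg, seg)
        assert np.isnan(out["symmetry_a"])


class TestExtractFeatures:
    def _signal(self, rng=None, lag=0):
        d = trapezoid(residual=1.0)
        d_r = np.concatenate([np.zeros(lag), d[: len(d) - lag]]) if lag else d
        if rng is not None:
            d = d + rng.normal(0, 0.05, len(d))
        return DisplacementSignal(d=d, d_left=d, d_right=d_r, frame_rate_hz=50.0,
                                  method="from_rest")

    def test_invariants_on_valid_episode(self, rng):
        feats, seg = extract_features(self._signal(rng, lag=3))
        assert feats.onset_ratio + feats.apex_ratio + feats.offset_ratio == pytest.approx(1.0, abs=1e-9)
        assert feats.total_duration == pytest.approx(
            feats.onset_duration + feats.apex_duration + feats.offset_duration, abs=1e-9)
        assert -1.0 <= feats.symmetry_a <= 1.0
        assert feats.symmetry_d == abs(feats.symmetry_c) >= 0
        assert feats.irregularity_b >= 0

    def test_feature_vector_order(self):
        feats, _ = extract_features(self._signal())
        vec = feats.as_vector()
        assert vec[0] == feats.onset_duration
        assert vec[-1] == feats.symmetry_d
        assert len(vec) == 17
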