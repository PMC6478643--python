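import numpy as np
import pytest

from gesturekin import (
    MINIMUM_JERK_PEAK_FACTOR,
    ActSpec,
    FeatureConfig,
    Posture,
    SpecError,
    Stroke,
    bin_peak_velocities,
    extract_features,
    generate_act,
    generate_dataset,
    minimum_jerk_segment,
)


class TestMinimumJerk:
    def test_degenerate_segments(self):
        seg = minimum_jerk_segment((0.1, 0.2, 0.3), (0.1, 0.2, 0.3), 0.5, 30)
        np.testing.assert_array_equal(seg, np.tile([0.1, 0.2, 0.3], (16, 1)))
        with pytest.raises(SpecError):
            minimum_jerk_segment((0, 0, 0), (1, 0, 0), 0.03, 30)

    def test_endpoints_exact(self):
        seg = minimum_jerk_segment((0, 0, 0), (0.3, -0.1, 0.2), 0.6, 30)
        np.testing.assert_array_equal(seg[0], [0, 0, 0])
        np.testing.assert_allclose(seg[-1], [0.3, -0.1, 0.2], atol=1e-15)

    @pytest.mark.parametrize("d,t,fps", [(0.3, 0.4, 30), (0.5, 0.6, 30), (0.8, 1.0, 30), (0.3, 0.4, 60)])
    def test_peak_speed_within_one_percent_of_analytic(self, d, t, fps):
        from conftest import speed_fourth_order

        seg = minimum_jerk_segment((0, 0, 0), (d, 0, 0), t, fps)
        np.testing.assert_allclose(
            speed_fourth_order(seg, fps).max(), MINIMUM_JERK_PEAK_FACTOR * d / t, rtol=0.01
        )

    def test_end_frames_are_nearly_still(self):
        # analytic end velocity is exactly zero; the first/last frame-average
        # displacement is O(D / n^2) and must be a tiny fraction of the peak
        seg = minimum_jerk_segment((0, 0, 0), (0.5, 0, 0), 0.6, 30)
        v = np.linalg.norm(np.diff(seg, axis=0), axis=1) * 30
        assert v[0] < 0.03 * v.max() and v[-1] < 0.03 * v.max()


def three_stroke_spec(jitter_sd=0.0, seed=0):
    up, down = (0.45, 1.15, 0.35), (0.30, 0.85, 0.25)
    return ActSpec(
        duration_s=9.0,
        strokes=[
            Stroke("R", 1.0, 0.6, up),
            Stroke("R", 2.0, 0.6, down),
            Stroke("R", 3.0, 0.6, up),
            Stroke("R", 4.0, 0.6, down),
        ][:3] + [Stroke("R", 4.2, 0.8, down)],
        holds=[(6.0, 0.4)],
        jitter_sd=jitter_sd,
        seed=seed,
    )


class TestGenerateAct:
    def test_end_to_end_recovery_of_strokes_and_hold(self):
        seq, truth = generate_act(three_stroke_spec())
        row = extract_features(seq).rows[0]
        assert truth.submovements == {"L": 0, "R": 4}
        assert row.submovements_right == truth.submovements["R"]
        assert row.submovements_left == 0
        assert row.hold_count == truth.hold_count == 1
        assert abs(row.hold_time_s - truth.hold_time_s) <= 1.0 / 30 + 1e-9
        # the realized still interval contains the scheduled 0.4 s freeze
        assert truth.hold_time_s >= 0.4
        assert row.vertical_amplitude == truth.vertical_amplitude == 2

    def test_sub_threshold_stroke_contributes_no_submovement(self):
        slow = ActSpec(
            duration_s=5.0,
            strokes=[Stroke("R", 1.0, 1.0, (0.33, 0.88, 0.27))],  # peak 0.1 m/s
        )
        seq, truth = generate_act(slow)
        assert truth.submovements["R"] == 0
        assert truth.peak_speed_mps < 0.2
        assert extract_features(seq).rows[0].submovements_right == 0

    def test_determinism_and_seed_sensitivity(self):
        a1, _ = generate_act(three_stroke_spec(jitter_sd=0.002, seed=5))
        a2, _ = generate_act(three_stroke_spec(jitter_sd=0.002, seed=5))
        b, _ = generate_act(three_stroke_spec(jitter_sd=0.002, seed=6))
        np.testing.assert_array_equal(a1.positions, a2.positions)
        assert not np.array_equal(a1.positions, b.positions)

    def test_truth_describes_noise_free_motion(self):
        _, clean = generate_act(three_stroke_spec())
        _, noisy = generate_act(three_stroke_spec(jitter_sd=0.002, seed=3))
        assert clean.submovements == noisy.submovements
        assert clean.hold_time_s == noisy.hold_time_s

    def test_overlapping_strokes_rejected(self):
        spec = three_stroke_spec()
        spec.strokes.append(Stroke("R", 1.2, 0.6, (0.5, 1.0, 0.3)))
        with pytest.raises(SpecError, match="overlap|chain"):
            generate_act(spec)

    def test_stroke_during_hold_rejected(self):
        spec = ActSpec(
            duration_s=5.0,
            strokes=[Stroke("R", 2.1, 0.6, (0.45, 1.15, 0.35))],
            holds=[(2.0, 0.5)],
        )
        with pytest.raises(SpecError, match="hold"):
            generate_act(spec)

    def test_teleporting_stroke_start_rejected(self):
        spec = ActSpec(
            duration_s=5.0,
            strokes=[Stroke("R", 1.0, 0.6, (0.45, 1.15, 0.35), start=(9.0, 9.0, 9.0))],
        )
        with pytest.raises(SpecError, match="chain"):
            generate_act(spec)

    def test_posture_must_order_landmarks(self):
        with pytest.raises(SpecError):
            Posture(spine_mid_y=1.4, neck_y=1.35, head_y=1.5)


class TestGenerateDataset:
    def test_same_seed_reproduces_truth_table(self):
        _, _, t1, _ = generate_dataset(n_acts=6, seed=9)
        _, _, t2, _ = generate_dataset(n_acts=6, seed=9)
        assert t1.equals(t2)

    def test_battery_spans_all_amplitude_categories_and_counts(self, battery):
        _, _, truth_df, _ = battery
        assert set(truth_df.vertical_amplitude) == {1, 2, 3, 4}
        assert set(truth_df.submovements_right) == {0, 1, 2, 3, 4, 5}
        assert set(truth_df.hold_count) == {0, 1, 2}

    def test_categories_recovered_by_extraction(self, battery, battery_features):
        _, _, truth_df, _ = battery
        df = battery_features.to_dataframe()
        assert df.vertical_amplitude.tolist() == truth_df.vertical_amplitude.tolist()

    def test_fourteen_act_peaks_fill_seven_bins_twice(self):
        seq, windows, truth_df, _ = generate_dataset(n_acts=14, seed=0)
        table = extract_features(seq, windows)
        peaks = table.to_dataframe().peak_velocity_mps.to_numpy()
        assert len(np.unique(peaks)) == 14
        bins = bin_peak_velocities(peaks, 7)
        assert np.bincount(bins, minlength=8)[1:].tolist() == [2] * 7
        # sorting oracle: bins follow the sorted order of the peaks
        order = np.argsort(peaks)
        assert bins[order].tolist() == sorted(bins.tolist())

    def test_csv_battery_round_trips(self, tmp_path):
        from gesturekin import read_act_windows, read_skeleton_table

        seq, windows, truth_df, _ = generate_dataset(n_acts=3, seed=2, out_dir=tmp_path)
        back = read_skeleton_table(tmp_path / "skeleton.csv", fps=30.0)
        np.testing.assert_allclose(back.positions, seq.positions, atol=1e-6)
        wins = read_act_windows(tmp_path / "windows.csv")
        assert [w.label for w in wins] == [w.label for w in windows]
        assert (tmp_path / "truth.csv").exists()
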