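import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gesturekin import (
    ActWindow,
    DataQualityError,
    FeatureConfig,
    Hold,
    SpeedSeries,
    accumulated_distance,
    bin_peak_velocities,
    detect_holds,
    detect_submovements,
    extract_features,
    hold_min_frames,
    hold_time,
    peak_velocity,
    vertical_amplitude,
)

from conftest import make_sequence, still_run_sequence


def series(values, fps=30.0, joint="HandRight"):
    return SpeedSeries(joint=joint, fps=fps, speed=np.asarray(values, dtype=float))


def brute_force_submovement_peaks(s, min_peak=0.2, min_sep=8):
    """Independent oracle: enumerate all strict local maxima, filter by
    height, then greedy separation by descending height (earlier wins ties)."""
    s = np.asarray(s, dtype=float)
    cands = [
        i
        for i in range(1, len(s) - 1)
        if s[i - 1] < s[i] > s[i + 1] and s[i] >= min_peak
    ]
    kept = []
    for p in sorted(cands, key=lambda i: (-s[i], i)):
        if all(abs(p - q) >= min_sep for q in kept):
            kept.append(p)
    return sorted(kept)


def bump(center, height, width, n):
    """A smooth velocity bell over a zero baseline."""
    f = np.arange(n)
    return height * np.exp(-0.5 * ((f - center) / width) ** 2)


class TestSubmovements:
    def test_flat_series_below_threshold_yields_none(self):
        assert detect_submovements(series(np.full(60, 0.1))) == []

    def test_two_separated_bumps_yield_two_peaks(self):
        s = bump(20, 0.5, 3, 80) + bump(50, 0.5, 3, 80)
        subs = detect_submovements(series(s))
        assert [sm.peak_frame for sm in subs] == [20, 50]
        assert all(sm.hand == "R" for sm in subs)
        assert all(sm.onset_frame <= sm.peak_frame <= sm.offset_frame for sm in subs)

    def test_close_peaks_keep_only_the_higher(self):
        s = np.zeros(60)
        s[18:23] = [0.2, 0.4, 0.5, 0.4, 0.2]  # peak 0.5 at 20
        s[23:28] = [0.3, 0.35, 0.4, 0.35, 0.2]  # peak 0.4 at 25, 5 frames away
        subs = detect_submovements(series(s))
        assert [sm.peak_frame for sm in subs] == [20]
        assert subs[0].peak_speed == 0.5

    def test_empty_series_is_empty_not_an_error(self):
        assert detect_submovements(series([])) == []

    def test_matches_bruteforce_on_random_series(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(5, 301))
            if rng.random() < 0.5:
                s = np.abs(np.cumsum(rng.normal(0, 0.05, n)))
            else:
                s = rng.uniform(0, 0.5, n)
            got = [sm.peak_frame for sm in detect_submovements(series(s))]
            assert got == brute_force_submovement_peaks(s)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0, 1.0, allow_nan=False, width=32), min_size=3, max_size=120),
        st.floats(1.0, 3.0),
    )
    def test_scaling_speed_up_never_loses_submovements(self, values, c):
        s = np.asarray(values, dtype=float)
        before = len(detect_submovements(series(s)))
        after = len(detect_submovements(series(c * s)))
        assert after >= before


class TestHolds:
    def test_nine_still_frames_at_30fps_is_one_hold_of_300ms(self):
        holds = detect_holds(still_run_sequence(9))
        assert len(holds) == 1
        assert holds[0].end_frame - holds[0].start_frame == 9
        np.testing.assert_allclose(holds[0].duration_s, 0.3)

    def test_eight_still_frames_is_no_hold(self):
        assert detect_holds(still_run_sequence(8)) == []

    def test_min_frames_matches_duration_times_fps(self):
        assert hold_min_frames(FeatureConfig(), 30.0) == 9
        assert hold_min_frames(FeatureConfig(), 25.0) == 8  # ceil(7.5)

    def test_single_moving_elbow_breaks_the_hold(self):
        seq = still_run_sequence(12)
        pos = seq.positions.copy()
        j = seq.joint_index["ElbowLeft"]
        pos[:, j, 0] = 0.02 * np.arange(seq.n_frames)  # moves every frame
        seq2 = seq.__class__(positions=pos, fps=seq.fps, joints=seq.joints)
        assert detect_holds(seq2) == []

    def test_missing_hold_joint_raises_data_quality_error(self):
        seq = still_run_sequence(12)
        pos = seq.positions.copy()
        pos[3, seq.joint_index["ThumbLeft"], :] = np.nan
        seq2 = seq.__class__(positions=pos, fps=seq.fps, joints=seq.joints)
        with pytest.raises(DataQualityError, match="ThumbLeft"):
            detect_holds(seq2)

    def test_holds_are_maximal_and_disjoint(self):
        seq = still_run_sequence(30, n_total=80, start=10)
        pos = seq.positions.copy()
        # carve a single moving frame inside the run to split it
        step = np.zeros(3)
        step[0] = 0.02
        pos[25:] += step
        seq2 = seq.__class__(positions=pos, fps=seq.fps, joints=seq.joints)
        holds = detect_holds(seq2)
        assert len(holds) == 2
        assert holds[0].end_frame <= holds[1].start_frame


class TestVerticalAmplitude:
    def _posture_seq(self, hand_y):
        n = len(hand_y)
        mk = lambda y: np.tile([0.0, y, 0.0], (n, 1))
        return make_sequence(
            {
                "SpineMid": mk(1.05),
                "Neck": mk(1.35),
                "Head": mk(1.50),
                "HandRight": np.stack(
                    [np.zeros(n), np.asarray(hand_y, float), np.zeros(n)], axis=1
                ),
            }
        )

    def test_hand_below_spine_mid_is_category_1(self):
        assert vertical_amplitude(self._posture_seq([0.8, 0.9, 1.0])) == 1

    def test_single_frame_above_head_is_category_4(self):
        assert vertical_amplitude(self._posture_seq([0.9, 1.55, 0.9])) == 4

    def test_peak_between_neck_and_head_is_category_3(self):
        assert vertical_amplitude(self._posture_seq([0.9, 1.40, 1.2])) == 3

    def test_raising_the_hand_cannot_decrease_the_category(self):
        ys = [0.9, 1.1, 1.3]
        base = vertical_amplitude(self._posture_seq(ys))
        for shift in (0.1, 0.3, 0.6):
            shifted = vertical_amplitude(self._posture_seq([y + shift for y in ys]))
            assert shifted >= base

    def test_disordered_landmarks_warn_but_proceed(self):
        n = 4
        mk = lambda y: np.tile([0.0, y, 0.0], (n, 1))
        seq = make_sequence(
            {
                "SpineMid": mk(1.5),  # above the head: invalid posture
                "Neck": mk(1.35),
                "Head": mk(1.0),
                "HandRight": mk(0.9),
            }
        )
        with pytest.warns(UserWarning, match="landmark"):
            vertical_amplitude(seq)


class TestPeakVelocityAndBinning:
    def test_peak_velocity_is_the_maximum(self):
        assert peak_velocity(series(np.full(20, 0.3))) == 0.3
        assert peak_velocity(series(np.zeros(20))) == 0.0
        spiked = np.zeros(20)
        spiked[7] = 1.2
        assert peak_velocity(series(spiked)) == 1.2
        with pytest.raises(ValueError):
            peak_velocity(series([]))

    def test_seven_increasing_values_fill_seven_bins(self):
        np.testing.assert_array_equal(
            bin_peak_velocities(np.linspace(0.2, 2.0, 7), 7), np.arange(1, 8)
        )

    def test_fourteen_values_give_two_per_bin(self):
        bins = bin_peak_velocities(np.linspace(0.2, 2.0, 14), 7)
        assert np.bincount(bins, minlength=8)[1:].tolist() == [2] * 7

    def test_ties_share_the_lower_bin(self):
        with pytest.warns(UserWarning):
            bins = bin_peak_velocities(np.ones(10), 7)
        assert set(bins) == {1}

    def test_binning_is_monotone_in_value(self):
        rng = np.random.default_rng(5)
        v = rng.uniform(0.1, 3.0, 40)
        bins = bin_peak_velocities(v, 7)
        order = np.argsort(v)
        assert np.all(np.diff(bins[order]) >= 0)

    def test_equal_width_mode(self):
        bins = bin_peak_velocities([0.0, 0.4, 1.0], 2, mode="width")
        assert bins.tolist() == [1, 1, 2]
        bins = bin_peak_velocities([0.0, 0.6, 1.0], 2, mode="width")
        assert bins.tolist() == [1, 2, 2]


class TestDistanceAndHoldTime:
    def test_stationary_hands_travel_nothing(self):
        seq = make_sequence({"HandLeft": np.zeros((20, 3)), "HandRight": np.zeros((20, 3))})
        assert accumulated_distance(seq) == 0.0

    def test_straight_line_distance(self):
        n = 31
        track = np.stack([np.linspace(0, 0.30, n), np.zeros(n), np.zeros(n)], axis=1)
        seq = make_sequence({"HandRight": track, "HandLeft": np.zeros((n, 3))})
        np.testing.assert_allclose(accumulated_distance(seq), 0.30)
        np.testing.assert_allclose(accumulated_distance(seq, "R"), 0.30)
        assert accumulated_distance(seq, "L") == 0.0

    def test_square_path_distance_is_perimeter(self):
        corners = np.array(
            [[0, 0, 0], [0.1, 0, 0], [0.1, 0.1, 0], [0, 0.1, 0], [0, 0, 0]], dtype=float
        )
        track = np.repeat(corners, 1, axis=0)
        seq = make_sequence({"HandRight": track, "HandLeft": np.zeros((5, 3))})
        np.testing.assert_allclose(accumulated_distance(seq), 0.4)

    def test_hold_time_adds_disjoint_durations(self):
        assert hold_time([]) == 0.0
        holds = [Hold(0, 9, 0.3), Hold(20, 35, 0.5)]
        np.testing.assert_allclose(hold_time(holds), 0.8)
        with pytest.raises(ValueError):
            hold_time([Hold(0, 10, 0.333), Hold(5, 20, 0.5)])


class TestExtractFeatures:
    def test_no_windows_yields_exactly_one_row(self, battery):
        seq, _, _, _ = battery
        table = extract_features(seq)
        assert len(table) == 1
        assert table.rows[0].label == "all"
        assert table.rows[0].peak_velocity_bin is None  # dataset-relative, needs >= 2 acts

    def test_rows_follow_windows_and_get_bins(self, battery_features, battery):
        _, windows, _, _ = battery
        df = battery_features.to_dataframe()
        assert list(df.act_label) == [w.label for w in windows]
        assert df.peak_velocity_bin.notna().all()
        assert df.peak_velocity_bin.between(1, 7).all()

    def test_per_act_errors_do_not_stop_other_acts(self, battery):
        seq, windows, _, _ = battery
        bad = ActWindow("beyond", seq.duration_s + 1.0, seq.duration_s + 2.0)
        table = extract_features(seq, [windows[0], bad])
        assert table.rows[0].error is None
        assert table.rows[1].error is not None
        assert np.isnan(table.rows[1].distance_m)

    def test_conservation_invariants_on_battery(self, battery_features, battery):
        _, windows, _, _ = battery
        for row, w in zip(battery_features.rows, windows):
            assert row.submovements_left + row.submovements_right == row.submovements_total
            assert row.hold_time_s <= w.duration_s + 1e-9
            assert row.hold_count >= 0
        for analysis in battery_features.analyses:
            for subs in analysis.submovements.values():
                for sm in subs:
                    assert sm.peak_speed >= 0.2
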