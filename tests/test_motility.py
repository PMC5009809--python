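import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_track, random_track
from nkcontacts.motility import (
    confinement_ratio,
    fov_average_speed,
    instantaneous_speed,
    mean_track_speed,
    normalized_speed,
    trace_length,
)
from nkcontacts.trackio import FieldOfView, Trajectory


def straight_track(speed_um_min=10.0, n=6, dt_s=60.0):
    step = speed_um_min * dt_s / 60.0
    xyz = np.zeros((n, 3))
    xyz[:, 0] = np.arange(n) * step
    return make_track("NK000", "NK", xyz, dt_s=dt_s)


class TestInstantaneousSpeed:
    def test_constant_velocity(self):
        track = make_track("NK000", "NK", [[0, 0, 0], [10, 0, 0]], dt_s=60.0)
        series = instantaneous_speed(track)
        assert np.allclose(series.v_um_min, [10.0, 10.0])

    def test_stationary_track(self):
        series = instantaneous_speed(make_track("NK000", "NK", np.zeros((5, 3))))
        assert np.all(series.v_um_min == 0.0)

    def test_matches_finite_difference_oracle(self, rng):
        track = random_track(rng, n=50)
        series = instantaneous_speed(track)
        for i in range(1, 50):
            expected = (
                np.linalg.norm(track.xyz[i] - track.xyz[i - 1])
                / (track.times_s[i] - track.times_s[i - 1])
                * 60.0
            )
            assert series.v_um_min[i] == pytest.approx(expected)
        assert series.v_um_min[0] == series.v_um_min[1]

    def test_single_point_rejected(self):
        track = Trajectory("NK000", "NK", [0], [0.0], np.zeros((1, 3)))
        with pytest.raises(ValueError, match="2"):
            instantaneous_speed(track)


class TestTraceLength:
    def test_straight_steps(self):
        xyz = [[0, 0, 0], [5, 0, 0], [10, 0, 0], [15, 0, 0]]
        track = make_track("NK000", "NK", xyz)
        assert trace_length(track, 3) == pytest.approx(15.0)

    def test_first_frame_is_zero(self, rng):
        track = random_track(rng)
        assert trace_length(track, int(track.frames[0])) == 0.0

    def test_matches_cumsum_oracle(self, rng):
        track = random_track(rng, n=40)
        steps = np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)
        for i in (1, 17, 39):
            assert trace_length(track, i) == pytest.approx(np.sum(steps[:i]))

    def test_out_of_range_frame(self, rng):
        with pytest.raises(ValueError, match="frame"):
            trace_length(random_track(rng, n=10), 99)


class TestConfinementRatio:
    def test_straight_line_is_one(self):
        series = confinement_ratio(straight_track())
        assert np.allclose(series.cr, 1.0)

    def test_closed_square_loop_returns_to_zero(self):
        xyz = [[0, 0, 0], [10, 0, 0], [10, 10, 0], [0, 10, 0], [0, 0, 0]]
        series = confinement_ratio(make_track("NK000", "NK", xyz))
        assert series.cr[-1] == 0.0

    def test_right_angle_path(self):
        xyz = [[0, 0, 0], [10, 0, 0], [10, 10, 0]]
        series = confinement_ratio(make_track("NK000", "NK", xyz))
        assert series.cr[-1] == pytest.approx(np.sqrt(200) / 20)

    def test_first_frame_convention(self, rng):
        assert confinement_ratio(random_track(rng)).cr[0] == 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 60))
    def test_cr_bounded_and_trace_monotone(self, seed, n):
        track = random_track(np.random.default_rng(seed), n=n)
        series = confinement_ratio(track)
        assert np.all(series.cr >= 0.0) and np.all(series.cr <= 1.0)
        assert np.all(np.diff(series.trace_len_um) >= 0)


class TestMeanAndFovSpeed:
    def test_constant_speed_exact(self):
        assert mean_track_speed(straight_track(10.0)) == 10.0

    def test_alternating_steps_average(self):
        xyz = np.zeros((5, 3))
        xyz[:, 0] = np.cumsum([0, 5, 15, 5, 15])
        assert mean_track_speed(make_track("NK000", "NK", xyz, dt_s=60.0)) == 10.0

    def test_matches_oracle_mean(self, rng):
        track = random_track(rng, n=30)
        v = instantaneous_speed(track).v_um_min
        assert mean_track_speed(track) == pytest.approx(np.mean(v[1:]))

    def test_two_track_fov_average(self):
        fov = FieldOfView(
            "F",
            "steady_state",
            60.0,
            [straight_track(8.0), straight_track(12.0)],
        )
        fov.trajectories[1].cell_id = "NK001"
        assert fov_average_speed(fov).v_fov_um_min == pytest.approx(10.0)

    def test_single_track_identity(self):
        fov = FieldOfView("F", "steady_state", 60.0, [straight_track(7.5)])
        assert fov_average_speed(fov).v_fov_um_min == pytest.approx(7.5)

    def test_two_stage_mean_oracle_and_permutation_invariance(self, rng):
        tracks = [random_track(rng, f"NK{i:03d}", n=20) for i in range(20)]
        fov = FieldOfView("F", "steady_state", 30.0, list(tracks))
        expected = np.mean([mean_track_speed(t) for t in tracks])
        assert fov_average_speed(fov).v_fov_um_min == pytest.approx(expected)
        shuffled = FieldOfView("F", "steady_state", 30.0, tracks[::-1])
        assert (
            fov_average_speed(shuffled).v_fov_um_min
            == fov_average_speed(fov).v_fov_um_min
        )

    def test_no_eligible_tracks(self):
        fov = FieldOfView("F", "steady_state", 60.0, [])
        with pytest.raises(ValueError, match="eligible"):
            fov_average_speed(fov)


class TestNormalizedSpeed:
    def _track_with_speeds(self, speeds_um_min):
        xyz = np.zeros((len(speeds_um_min) + 1, 3))
        xyz[1:, 0] = np.cumsum(speeds_um_min)  # dt = 60 s, so step == speed
        return make_track("NK000", "NK", xyz, dt_s=60.0)

    def test_inclusive_boundary_zeroes(self):
        track = self._track_with_speeds([6.0])
        series = normalized_speed(track, v_fov_um_min=10.0, alpha=0.6)
        assert np.all(series.v_norm == 0.0)

    def test_just_above_boundary(self):
        track = self._track_with_speeds([6.0, 6.1])
        series = normalized_speed(track, v_fov_um_min=10.0, alpha=0.6)
        assert series.v_norm[1] == 0.0
        assert series.v_norm[2] == pytest.approx(0.61)

    def test_zero_set_equals_criterion_set(self, rng):
        track = random_track(rng, n=40)
        series = normalized_speed(track, v_fov_um_min=10.0, alpha=0.6)
        assert np.array_equal(series.v_norm == 0.0, series.v_um_min <= 6.0)

    def test_stationary_frame_is_zero(self):
        track = self._track_with_speeds([0.0, 12.0])
        series = normalized_speed(track, v_fov_um_min=10.0)
        assert series.v_norm[1] == 0.0

    def test_invalid_fov_speed(self, rng):
        with pytest.raises(ValueError, match="v_fov"):
            normalized_speed(random_track(rng), v_fov_um_min=0.0)
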