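import numpy as np
import pytest

from conftest import make_track, random_track
from oracles import enumerate_events, random_criteria
from nkcontacts.detection import (
    classify_duration,
    confinement_criterion,
    detect_all,
    detect_events,
    distance_only_events,
    events_from_criteria,
    pair_distance,
    speed_criterion,
)
from nkcontacts.motility import fov_average_speed
from nkcontacts.trackio import DetectorConfig, FieldOfView


CFG = DetectorConfig()


def run_detector(frames, cd, cs, cc, config=CFG, dt=30.0):
    events = events_from_criteria(
        np.asarray(frames), np.asarray(cd), np.asarray(cs), np.asarray(cc), config, dt
    )
    return [(e.start_frame, e.end_frame, e.n_frames, e.n_tolerated_frames) for e in events]


class TestPairDistance:
    def test_3_4_5_triangle(self):
        nk = make_track("NK000", "NK", np.zeros((2, 3)))
        dc = make_track("DC000", "DC", np.tile([3.0, 4.0, 0.0], (2, 1)))
        series = pair_distance(nk, dc, 25.0)
        assert np.allclose(series.dist_um, 5.0)
        assert series.met.all()

    def test_identical_positions(self):
        nk = make_track("NK000", "NK", np.zeros((3, 3)))
        dc = make_track("DC000", "DC", np.zeros((3, 3)))
        series = pair_distance(nk, dc, 25.0)
        assert np.all(series.dist_um == 0.0) and series.met.all()

    def test_no_shared_frames_is_empty(self):
        nk = make_track("NK000", "NK", np.zeros((3, 3)), frames=[0, 1, 2])
        dc = make_track("DC000", "DC", np.zeros((3, 3)), frames=[10, 11, 12])
        assert pair_distance(nk, dc, 25.0).is_empty

    def test_matches_per_frame_oracle(self, rng):
        nk = random_track(rng, "NK000", "NK", n=40)
        dc = random_track(rng, "DC000", "DC", n=40, step_um=0.3)
        series = pair_distance(nk, dc, 25.0)
        for i, f in enumerate(series.frames):
            expected = np.linalg.norm(nk.xyz[f] - dc.xyz[f])
            assert series.dist_um[i] == pytest.approx(expected)
            assert series.met[i] == (expected <= 25.0)

    def test_dist_d_plot_values(self):
        nk = make_track("NK000", "NK", np.zeros((2, 3)))
        dc = make_track("DC000", "DC", np.tile([30.0, 0.0, 0.0], (2, 1)))
        assert np.all(pair_distance(nk, dc, 25.0).dist_d == 0.0)
        near = make_track("DC001", "DC", np.tile([3.0, 0.0, 0.0], (2, 1)))
        assert np.all(pair_distance(nk, near, 25.0).dist_d == -0.15)


class TestCriteria:
    def test_decreasing_cr_meets(self):
        assert confinement_criterion(np.array([1.0, 0.9, 0.8]), 0.01).tolist() == [
            False,
            True,
            True,
        ]

    def test_increasing_cr_fails(self):
        assert confinement_criterion(np.array([0.5, 0.6]), 0.01).tolist() == [
            False,
            False,
        ]

    def test_increase_within_tolerance_meets(self):
        eps = 0.01
        assert confinement_criterion(np.array([0.5, 0.5 + eps / 2]), eps)[1]

    def test_speed_inclusive_boundary(self):
        v = np.array([6.0, 6.0001, 0.0])
        assert speed_criterion(v, 10.0, 0.6).tolist() == [True, False, True]

    def test_speed_requires_positive_fov_average(self):
        with pytest.raises(ValueError):
            speed_criterion(np.array([1.0]), 0.0)


class TestEventSegmentation:
    def _full(self, n):
        t = np.ones(n, dtype=bool)
        return t.copy(), t.copy(), t.copy()

    def test_single_isolated_single_criterion_failure_absorbed(self):
        frames = np.arange(3, 11)
        cd, cs, cc = self._full(8)
        cs[3] = False  # frame 6: only the speed criterion fails
        assert run_detector(frames, cd, cs, cc) == [(3, 10, 8, 1)]

    def test_two_consecutive_failures_split_event(self):
        frames = np.arange(3, 11)
        cd, cs, cc = self._full(8)
        cs[3] = cs[4] = False  # frames 6 and 7
        assert run_detector(frames, cd, cs, cc) == [(3, 5, 3, 0), (8, 10, 3, 0)]

    def test_two_criterion_failure_not_absorbed(self):
        frames = np.arange(3, 11)
        cd, cs, cc = self._full(8)
        cs[3] = cc[3] = False
        assert run_detector(frames, cd, cs, cc) == [(3, 5, 3, 0), (7, 10, 4, 0)]

    def test_edge_failure_not_absorbed(self):
        frames = np.arange(5)
        cd, cs, cc = self._full(5)
        cd[0] = False
        assert run_detector(frames, cd, cs, cc) == [(1, 4, 4, 0)]

    def test_no_qualifying_frames(self):
        frames = np.arange(6)
        cd, cs, cc = self._full(6)
        cd[:] = False
        assert run_detector(frames, cd, cs, cc) == []

    def test_gap_breaks_run_even_with_tolerance(self):
        frames = np.array([0, 1, 2, 4, 5, 6])  # frame 3 missing
        cd, cs, cc = self._full(6)
        assert run_detector(frames, cd, cs, cc) == [(0, 2, 3, 0), (4, 6, 3, 0)]

    def test_tolerance_disabled(self):
        frames = np.arange(3, 11)
        cd, cs, cc = self._full(8)
        cs[3] = False
        cfg = DetectorConfig(tolerance_enabled=False)
        assert run_detector(frames, cd, cs, cc, cfg) == [(3, 5, 3, 0), (7, 10, 4, 0)]

    def test_matches_interval_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(1, 26))
            frames, cd, cs, cc = random_criteria(rng, n)
            for tol in (True, False):
                cfg = DetectorConfig(tolerance_enabled=tol)
                got = run_detector(frames, cd, cs, cc, cfg)
                assert got == enumerate_events(frames, cd, cs, cc, tol)

    def test_tolerance_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            frames, cd, cs, cc = random_criteria(rng, int(rng.integers(2, 30)))
            off = run_detector(frames, cd, cs, cc, DetectorConfig(tolerance_enabled=False))
            on = run_detector(frames, cd, cs, cc, DetectorConfig(tolerance_enabled=True))
            assert sum(e[2] for e in on) >= sum(e[2] for e in off)
            for s, e, *_ in off:
                assert any(s2 <= s and e2 >= e for s2, e2, *_ in on)


class TestClassification:
    @pytest.mark.parametrize(
        "duration,expected",
        [
            (930.0, "long"),
            (900.0, "long"),
            (899.9, "intermediate"),
            (300.0, "intermediate"),
            (5.0, "intermediate"),
            (4.0, "touch_and_go"),
        ],
    )
    def test_duration_classes(self, duration, expected):
        assert classify_duration(duration, CFG) == expected


def _contact_fixture(contact_frames, n=20, dt=30.0, nk_speed=12.0):
    """NK approaches a static DC, stops beside it on the given frames."""
    dc_pos = np.array([100.0, 0.0, 0.0])
    xyz = np.zeros((n, 3))
    pos = np.array([0.0, 0.0, 0.0])
    step = nk_speed * dt / 60.0
    for f in range(1, n):
        if f in contact_frames:
            pos = dc_pos + np.array([2.0, 0.0, 0.0])  # parked by the DC
        elif f > max(contact_frames):
            pos = pos + np.array([0.0, step, 0.0])
        else:
            pos = pos + np.array([step, 0.0, 0.0])
        xyz[f] = pos
    nk = make_track("NK000", "NK", xyz, dt_s=dt)
    dc = make_track("DC000", "DC", np.tile(dc_pos, (n, 1)), dt_s=dt)
    return nk, dc


class TestDetectAll:
    def test_distant_pair_yields_nothing(self):
        nk = make_track("NK000", "NK", np.zeros((5, 3)))
        dc = make_track("DC000", "DC", np.tile([300.0, 0, 0], (5, 1)))
        fov = FieldOfView("F", "steady_state", 30.0, [nk, dc])
        assert detect_all(fov, CFG) == []

    def test_constructed_contact_bounds(self):
        nk, dc = _contact_fixture(set(range(6, 13)))
        fov = FieldOfView("F", "steady_state", 30.0, [nk, dc])
        events = detect_all(fov, CFG)
        assert len(events) == 1
        assert (events[0].start_frame, events[0].end_frame) == (7, 12)
        assert events[0].duration_s == 6 * 30.0

    def test_gating_does_not_change_results(self, rng):
        tracks = [random_track(rng, f"NK{i:03d}", "NK", n=30, step_um=6) for i in range(5)]
        tracks += [random_track(rng, f"DC{i:03d}", "DC", n=30, step_um=0.3) for i in range(3)]
        fov = FieldOfView("F", "steady_state", 30.0, tracks)
        assert detect_all(fov, CFG, gate=True) == detect_all(fov, CFG, gate=False)

    def test_order_invariance(self, rng):
        tracks = [random_track(rng, f"NK{i:03d}", "NK", n=30, step_um=6) for i in range(4)]
        tracks += [random_track(rng, f"DC{i:03d}", "DC", n=30, step_um=0.3) for i in range(2)]
        fov = FieldOfView("F", "steady_state", 30.0, list(tracks))
        shuffled = FieldOfView("F", "steady_state", 30.0, tracks[::-1])
        assert detect_all(fov, CFG) == detect_all(shuffled, CFG)

    def test_requires_both_cell_types(self, rng):
        fov = FieldOfView("F", "steady_state", 30.0, [random_track(rng)])
        with pytest.raises(ValueError, match="DC"):
            detect_all(fov, CFG)

    def test_threshold_monotonicity(self, rng):
        for _ in range(10):
            nk, dc = _contact_fixture(set(range(5, 11)), nk_speed=float(rng.uniform(8, 14)))
            fov = FieldOfView("F", "steady_state", 30.0, [nk, dc])
            base = sum(e.n_frames for e in detect_all(fov, CFG))
            wider = sum(
                e.n_frames
                for e in detect_all(fov, DetectorConfig(distance_threshold_um=35.0))
            )
            faster = sum(
                e.n_frames for e in detect_all(fov, DetectorConfig(speed_fraction=0.8))
            )
            assert wider >= base and faster >= base


class TestDistanceOnlyBaseline:
    def test_simple_on_run(self):
        frames = np.arange(4)
        nk = make_track("NK000", "NK", np.zeros((4, 3)))
        dc_x = np.array([30.0, 20.0, 20.0, 30.0])
        dc = make_track("DC000", "DC", np.column_stack([dc_x, np.zeros((4, 2))]))
        result = distance_only_events(nk, dc, 25.0, 30.0)
        assert [(e.start_frame, e.end_frame, e.n_frames) for e in result.events] == [
            (1, 2, 2)
        ]
        assert result.on.tolist() == [False, True, True, False]

    def test_never_close_no_events(self):
        nk = make_track("NK000", "NK", np.zeros((5, 3)))
        dc = make_track("DC000", "DC", np.tile([80.0, 0, 0], (5, 1)))
        assert distance_only_events(nk, dc, 25.0, 30.0).events == []

    def test_pass_by_overcalled_by_baseline_only(self):
        # NK cruises straight past the DC at full speed: proximity holds for
        # several frames but the cell never slows, so the three-criterion
        # detector stays silent while the distance-only baseline fires.
        n = 20
        xyz = np.zeros((n, 3))
        xyz[:, 0] = np.arange(n) * 5.0  # 10 μm/min at 30 s frames
        nk = make_track("NK000", "NK", xyz)
        dc = make_track("DC000", "DC", np.tile([47.0, 10.0, 0.0], (n, 1)))
        fov = FieldOfView("F", "steady_state", 30.0, [nk, dc])
        summary = fov_average_speed(fov)
        naive = distance_only_events(nk, dc, 25.0, 30.0)
        assert len(naive.events) >= 1
        assert detect_events(nk, dc, summary, CFG, 30.0) == []
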