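import numpy as np
import pytest

from conftest import make_track
from oracles import ttest_closed_form
from nkcontacts.cohort import (
    compare_conditions,
    duration_summary,
    interacting_fraction,
    long_fraction,
    summarize_cohort,
    velocity_summary,
)
from nkcontacts.detection import InteractionEvent
from nkcontacts.trackio import FieldOfView


def event(nk_id, dc_id="DC000", duration_s=300.0, cls="intermediate", fov_id="F"):
    n = max(int(duration_s // 30), 1)
    return InteractionEvent(
        fov_id=fov_id,
        nk_id=nk_id,
        dc_id=dc_id,
        start_frame=0,
        end_frame=n - 1,
        n_frames=n,
        duration_s=duration_s,
        n_tolerated_frames=0,
        event_class=cls,
    )


def nk_fov(n_nk, speeds=None, fov_id="F", condition="steady_state"):
    tracks = []
    for i in range(n_nk):
        v = 10.0 if speeds is None else speeds[i]
        xyz = np.zeros((5, 3))
        xyz[:, 0] = np.arange(5) * v / 2.0  # 30 s frames
        tracks.append(make_track(f"NK{i:03d}", "NK", xyz))
    return FieldOfView(fov_id, condition, 30.0, tracks)


class TestInteractingFraction:
    def test_nine_of_twenty(self):
        fov = nk_fov(20)
        events = [event(f"NK{i:03d}") for i in range(9)]
        assert interacting_fraction(events, fov) == 45.0

    def test_no_events_and_all_events(self):
        fov = nk_fov(4)
        assert interacting_fraction([], fov) == 0.0
        events = [event(f"NK{i:03d}") for i in range(4)]
        assert interacting_fraction(events, fov) == 100.0

    def test_invariant_to_splitting_across_dcs(self):
        fov = nk_fov(10)
        merged = [event("NK000", "DC000", 600.0)]
        split = [event("NK000", "DC000", 300.0), event("NK000", "DC001", 300.0)]
        assert interacting_fraction(merged, fov) == interacting_fraction(split, fov)

    def test_extra_noninteracting_track_dilutes(self):
        events = [event("NK000")]
        assert interacting_fraction(events, nk_fov(5)) > interacting_fraction(
            events, nk_fov(6)
        )

    def test_no_nk_tracks_rejected(self):
        fov = FieldOfView("F", "steady_state", 30.0, [])
        with pytest.raises(ValueError):
            interacting_fraction([], fov)


class TestLongFraction:
    def test_six_of_fifty(self):
        events = [
            event(f"NK{i:03d}", cls="long" if i < 6 else "intermediate",
                  duration_s=1000.0 if i < 6 else 100.0)
            for i in range(50)
        ]
        result = long_fraction(events)
        assert result.value_pct == 12.0 and result.defined

    def test_no_long_and_all_long(self):
        assert long_fraction([event("NK000")]).value_pct == 0.0
        alll = [event("NK000", cls="long", duration_s=1000.0)]
        assert long_fraction(alll).value_pct == 100.0

    def test_empty_is_flagged_undefined(self):
        result = long_fraction([])
        assert result.value_pct == 0.0 and not result.defined

    def test_cell_classified_by_longest_event(self):
        events = [
            event("NK000", "DC000", 100.0, "intermediate"),
            event("NK000", "DC001", 1000.0, "long"),
        ]
        assert long_fraction(events).value_pct == 100.0


class TestDurationSummary:
    def test_analytic_mean_and_sem(self):
        events = [event("NK000", duration_s=d) for d in (100.0, 200.0, 300.0)]
        s = duration_summary(events)
        assert s.mean_s == pytest.approx(200.0)
        assert s.sem_s == pytest.approx(57.735, abs=1e-3)

    def test_single_event_sem_missing(self):
        s = duration_summary([event("NK000")])
        assert s.mean_s == 300.0 and s.sem_s is None

    def test_empty_summary(self):
        s = duration_summary([])
        assert s.is_empty and s.mean_s is None

    def test_matches_bruteforce(self, rng):
        durations = rng.uniform(30, 2000, size=25)
        events = [event(f"NK{i:03d}", duration_s=d) for i, d in enumerate(durations)]
        s = duration_summary(events)
        assert s.mean_s == pytest.approx(durations.mean())
        assert s.sem_s == pytest.approx(
            durations.std(ddof=1) / np.sqrt(len(durations))
        )


class TestVelocitySummary:
    def test_two_constant_cells(self):
        fov = nk_fov(2, speeds=[8.0, 12.0])
        out = velocity_summary(fov, {"NK000", "NK001"})
        assert out == {"NK000": pytest.approx(8.0), "NK001": pytest.approx(12.0)}

    def test_empty_id_set(self):
        assert velocity_summary(nk_fov(3), set()) == {}

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="NK999"):
            velocity_summary(nk_fov(2), {"NK999"})


class TestCompareConditions:
    def test_identical_samples(self):
        r = compare_conditions([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == 1.0

    def test_zero_variance_flagged(self):
        r = compare_conditions([0, 0, 0, 0], [1, 1, 1, 1])
        assert r.degenerate and np.isnan(r.t)

    def test_matches_closed_form(self, rng):
        a = rng.normal(10, 2, 30)
        b = rng.normal(8, 2, 25)
        r = compare_conditions(a, b)
        t, p = ttest_closed_form(a, b)
        assert r.t == pytest.approx(t) and r.p == pytest.approx(p)
        assert 0 <= r.p <= 1

    def test_symmetry_up_to_sign(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(1, 1, 15)
        r1, r2 = compare_conditions(a, b), compare_conditions(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])


class TestSummarizeCohort:
    def test_counts_and_both_long_denominators(self):
        fov = nk_fov(20)
        events = [event(f"NK{i:03d}") for i in range(9)]
        events[0] = event("NK000", duration_s=1000.0, cls="long")
        summary = summarize_cohort([fov], events, "steady_state")
        assert summary.n_nk_tracked == 20
        assert summary.interacting_fraction_pct == 45.0
        assert summary.long_fraction_of_interacting_pct == pytest.approx(100 / 9)
        assert summary.long_fraction_of_tracked_pct == pytest.approx(5.0)
        assert summary.n_nk_interacting >= summary.n_long_cells
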