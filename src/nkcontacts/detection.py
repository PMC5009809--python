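"""Three-criterion, tolerance-refined detection of NK-DC interaction events.

An NK cell is called *interacting* with a DC at frame t_i when three
per-frame criteria hold simultaneously:

1. distance:   the 3D centroid distance Dist(t_i) <= d       (default 25 μm)
2. speed:      v_NK(t_i) <= α * V_FOV                         (default α = 0.60)
3. confinement: CR(t_i) <= CR(t_{i-1}) + ε_CR                 (default ε = 0.01),
   i.e. the confinement ratio is locally constant or decreasing.

An interaction *event* is a maximal run of consecutive shared frames on
which all three criteria hold, refined by a tolerance rule: a single
interior frame at which exactly ONE criterion fails, flanked on both sides
by fully qualifying frames, is absorbed into the run (it counts toward the
event length and is tallied in ``n_tolerated_frames``).  Two consecutive
failing frames always split an event, as does any tracking gap.

Event duration is ``n_frames * frame_interval_s`` — a one-frame contact
lasts one frame interval, not zero — and events are classed as
touch-and-go (< 5 s), long (>= 900 s, i.e. >= 15 min) or intermediate.

A distance-only baseline (:func:`distance_only_events`) is provided for
comparison; it systematically over-calls contacts because a fast cell
merely passing near a DC satisfies proximity without slowing or confining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motility import (
    FovSpeedSummary,
    confinement_ratio,
    fov_average_speed,
    instantaneous_speed,
)
from .trackio import DetectorConfig, FieldOfView, Trajectory

__all__ = [
    "DistanceSeries",
    "CriterionSeries",
    "InteractionEvent",
    "pair_distance",
    "confinement_criterion",
    "speed_criterion",
    "criterion_series",
    "events_from_criteria",
    "detect_events",
    "detect_all",
    "classify_duration",
    "classify_event",
    "distance_only_events",
    "events_to_frame",
    "pair_diagnostics",
]

#: plot constants for the digitized distance (figure parity only;
#: detection logic uses the boolean flag)
DIST_D_MET = -0.15
DIST_D_NOT_MET = 0.0


@dataclass
class DistanceSeries:
    """NK-DC centroid distance on the frames shared by both tracks."""

    frames: np.ndarray
    dist_um: np.ndarray
    met: np.ndarray  # bool, inclusive threshold dist <= d

    @property
    def dist_d(self) -> np.ndarray:
        """Digitized distance for plotting: -0.15 where met, 0 elsewhere."""
        return np.where(self.met, DIST_D_MET, DIST_D_NOT_MET)

    @property
    def is_empty(self) -> bool:
        return len(self.frames) == 0


@dataclass
class CriterionSeries:
    """Per-frame diagnostics and criterion booleans for one NK-DC pair."""

    nk_id: str
    dc_id: str
    frames: np.ndarray
    dist_um: np.ndarray
    v_um_min: np.ndarray
    v_norm: np.ndarray
    cr: np.ndarray
    c_dist: np.ndarray
    c_speed: np.ndarray
    c_conf: np.ndarray

    @property
    def n_met(self) -> np.ndarray:
        return (
            self.c_dist.astype(int) + self.c_speed.astype(int) + self.c_conf.astype(int)
        )


@dataclass
class InteractionEvent:
    """A maximal qualifying run of frames for one NK-DC pair."""

    fov_id: str
    nk_id: str
    dc_id: str
    start_frame: int
    end_frame: int
    n_frames: int
    duration_s: float
    n_tolerated_frames: int
    event_class: str  # touch_and_go | intermediate | long


def pair_distance(
    nk: Trajectory, dc: Trajectory, d: float = 25.0
) -> DistanceSeries:
    """Euclidean 3D NK-DC distance on shared frames, with the inclusive
    proximity flag.  Frames present in only one track are absent from the
    series; no shared frames yields an empty series (not an exception)."""
    shared, ink, idc = np.intersect1d(nk.frames, dc.frames, return_indices=True)
    dist = np.linalg.norm(nk.xyz[ink] - dc.xyz[idc], axis=1)
    return DistanceSeries(frames=shared, dist_um=dist, met=dist <= d)


def confinement_criterion(cr: np.ndarray, cr_tolerance: float = 0.01) -> np.ndarray:
    """Local non-increase of the confinement ratio, with tolerance.

    C_conf(t_i) is true iff CR(t_i) <= CR(t_{i-1}) + ε_CR; the first frame
    has no predecessor and is false by convention.
    """
    cr = np.asarray(cr, dtype=float)
    out = np.zeros(len(cr), dtype=bool)
    if len(cr) > 1:
        out[1:] = cr[1:] <= cr[:-1] + cr_tolerance
    return out


def speed_criterion(
    v_um_min: np.ndarray, v_fov_um_min: float, alpha: float = 0.60
) -> np.ndarray:
    """Inclusive upper speed threshold: v(t_i) <= alpha * V_FOV."""
    if v_fov_um_min <= 0:
        raise ValueError("v_fov_um_min must be > 0")
    return np.asarray(v_um_min, dtype=float) <= alpha * v_fov_um_min


def criterion_series(
    nk: Trajectory,
    dc: Trajectory,
    fov_summary: FovSpeedSummary,
    config: DetectorConfig,
) -> CriterionSeries:
    """Assemble the three per-frame criteria for one NK-DC pair.

    Speed and confinement ratio are computed on the full NK track (they are
    properties of the NK cell alone) and then restricted to the shared
    frames.  The confinement criterion at the pair's first shared frame is
    set false: there is no preceding value inside the pair series.
    """
    shared, ink, _ = np.intersect1d(nk.frames, dc.frames, return_indices=True)
    dist_series = pair_distance(nk, dc, config.distance_threshold_um)

    speed = instantaneous_speed(nk)
    v_fov = fov_summary.v_fov_um_min
    c_speed_full = speed_criterion(speed.v_um_min, v_fov, config.speed_fraction)
    v_norm_full = np.where(
        c_speed_full, 0.0, speed.v_um_min / v_fov if v_fov > 0 else np.nan
    )

    conf = confinement_ratio(nk)
    c_conf_full = confinement_criterion(conf.cr, config.cr_tolerance)

    c_conf = c_conf_full[ink]
    if len(c_conf):
        c_conf = c_conf.copy()
        c_conf[0] = False

    return CriterionSeries(
        nk_id=nk.cell_id,
        dc_id=dc.cell_id,
        frames=shared,
        dist_um=dist_series.dist_um,
        v_um_min=speed.v_um_min[ink],
        v_norm=v_norm_full[ink],
        cr=conf.cr[ink],
        c_dist=dist_series.met,
        c_speed=c_speed_full[ink],
        c_conf=c_conf,
    )


def classify_duration(duration_s: float, config: DetectorConfig) -> str:
    """touch_and_go iff duration < touch_and_go_s; long iff duration >=
    long_threshold_s; intermediate otherwise."""
    if duration_s < config.touch_and_go_s:
        return "touch_and_go"
    if duration_s >= config.long_threshold_s:
        return "long"
    return "intermediate"


def classify_event(event: InteractionEvent, config: DetectorConfig) -> str:
    return classify_duration(event.duration_s, config)


def events_from_criteria(
    frames: np.ndarray,
    c_dist: np.ndarray,
    c_speed: np.ndarray,
    c_conf: np.ndarray,
    config: DetectorConfig,
    frame_interval_s: float,
    fov_id: str = "",
    nk_id: str = "",
    dc_id: str = "",
) -> list[InteractionEvent]:
    """Segment a criterion sequence into maximal events.

    The run/absorption semantics: a frame belongs to an event when all
    three criteria hold, or (tolerance enabled) when exactly one fails and
    both the previous and next frames exist, are frame-contiguous and fully
    qualify.  Runs never bridge non-consecutive frame numbers (gaps break).
    """
    frames = np.asarray(frames, dtype=np.int64)
    n = len(frames)
    all3 = (
        np.asarray(c_dist, bool) & np.asarray(c_speed, bool) & np.asarray(c_conf, bool)
    )
    n_met = (
        np.asarray(c_dist, bool).astype(int)
        + np.asarray(c_speed, bool).astype(int)
        + np.asarray(c_conf, bool).astype(int)
    )
    ok = all3.copy()
    tolerated = np.zeros(n, dtype=bool)
    if config.tolerance_enabled:
        for i in range(1, n - 1):
            if (
                not all3[i]
                and n_met[i] == 2
                and all3[i - 1]
                and all3[i + 1]
                and frames[i] - frames[i - 1] == 1
                and frames[i + 1] - frames[i] == 1
            ):
                ok[i] = True
                tolerated[i] = True

    events: list[InteractionEvent] = []
    i = 0
    while i < n:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and ok[j + 1] and frames[j + 1] == frames[j] + 1:
            j += 1
        n_frames = j - i + 1
        duration = n_frames * frame_interval_s
        events.append(
            InteractionEvent(
                fov_id=fov_id,
                nk_id=nk_id,
                dc_id=dc_id,
                start_frame=int(frames[i]),
                end_frame=int(frames[j]),
                n_frames=n_frames,
                duration_s=float(duration),
                n_tolerated_frames=int(np.sum(tolerated[i : j + 1])),
                event_class=classify_duration(duration, config),
            )
        )
        i = j + 1
    return events


def detect_events(
    nk: Trajectory,
    dc: Trajectory,
    fov_summary: FovSpeedSummary,
    config: DetectorConfig,
    frame_interval_s: float,
    fov_id: str = "",
) -> list[InteractionEvent]:
    """Detect interaction events for one NK-DC pair (sorted by start frame)."""
    series = criterion_series(nk, dc, fov_summary, config)
    return events_from_criteria(
        series.frames,
        series.c_dist,
        series.c_speed,
        series.c_conf,
        config,
        frame_interval_s,
        fov_id=fov_id,
        nk_id=nk.cell_id,
        dc_id=dc.cell_id,
    )


def detect_all(
    fov: FieldOfView, config: DetectorConfig, gate: bool = True
) -> list[InteractionEvent]:
    """Detect events over all NK x DC pairs of a field of view.

    ``gate`` skips pairs whose minimum shared-frame distance never drops
    below 2d.  Events require distance <= d, so the gate is purely an
    optimization and cannot change results.  Output ordering is
    deterministic: (nk_id, dc_id, start_frame).
    """
    nks = sorted(fov.nk_tracks, key=lambda t: t.cell_id)
    dcs = sorted(fov.dc_tracks, key=lambda t: t.cell_id)
    if not nks or not dcs:
        raise ValueError(
            f"FOV {fov.fov_id!r} needs >= 1 NK and >= 1 DC track "
            f"({len(nks)} NK, {len(dcs)} DC found)"
        )
    summary = fov_average_speed(fov, {"NK"})
    events: list[InteractionEvent] = []
    for nk in nks:
        if nk.n_points < 2:
            continue
        for dc in dcs:
            dist = pair_distance(nk, dc, config.distance_threshold_um)
            if dist.is_empty:
                continue
            if gate and np.min(dist.dist_um) > 2 * config.distance_threshold_um:
                continue
            events.extend(
                detect_events(
                    nk, dc, summary, config, fov.frame_interval_s, fov_id=fov.fov_id
                )
            )
    events.sort(key=lambda e: (e.nk_id, e.dc_id, e.start_frame))
    return events


@dataclass
class DistanceOnlyResult:
    """Distance-only baseline: T_on/T_off series and naive events."""

    series: DistanceSeries
    on: np.ndarray  # bool per shared frame: Dist(t_i) <= d
    events: list[InteractionEvent]


def distance_only_events(
    nk: Trajectory,
    dc: Trajectory,
    d: float,
    frame_interval_s: float,
    fov_id: str = "",
    config: DetectorConfig | None = None,
) -> DistanceOnlyResult:
    """Simplified baseline using the proximity criterion alone.

    Naive events are maximal on-runs of the distance flag (gaps break; no
    tolerance — the tolerance rule is defined for the three-criterion
    detector).  This baseline over-calls interactions: it fires on cells
    that merely pass by a DC at full speed.
    """
    config = config or DetectorConfig()
    series = pair_distance(nk, dc, d)
    true_arr = np.ones(len(series.frames), dtype=bool)
    naive_cfg = DetectorConfig(
        distance_threshold_um=d,
        long_threshold_s=config.long_threshold_s,
        touch_and_go_s=config.touch_and_go_s,
        tolerance_enabled=False,
    )
    events = events_from_criteria(
        series.frames,
        series.met,
        true_arr,
        true_arr,
        naive_cfg,
        frame_interval_s,
        fov_id=fov_id,
        nk_id=nk.cell_id,
        dc_id=dc.cell_id,
    )
    return DistanceOnlyResult(series=series, on=series.met.copy(), events=events)


def events_to_frame(
    events: list[InteractionEvent], condition_by_fov: dict[str, str] | None = None
) -> pd.DataFrame:
    """Events as a flat table (the TSV export layout)."""
    condition_by_fov = condition_by_fov or {}
    return pd.DataFrame(
        [
            {
                "fov_id": e.fov_id,
                "condition": condition_by_fov.get(e.fov_id, ""),
                "nk_id": e.nk_id,
                "dc_id": e.dc_id,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "n_frames": e.n_frames,
                "n_tolerated_frames": e.n_tolerated_frames,
                "duration_s": e.duration_s,
                "class": e.event_class,
            }
            for e in events
        ],
        columns=[
            "fov_id",
            "condition",
            "nk_id",
            "dc_id",
            "start_frame",
            "end_frame",
            "n_frames",
            "n_tolerated_frames",
            "duration_s",
            "class",
        ],
    )


def pair_diagnostics(
    nk: Trajectory,
    dc: Trajectory,
    fov_summary: FovSpeedSummary,
    config: DetectorConfig,
) -> pd.DataFrame:
    """Per-frame diagnostics for one pair — enough to redraw the criterion
    timeline plots (CR, v_norm, digitized distance)."""
    s = criterion_series(nk, dc, fov_summary, config)
    return pd.DataFrame(
        {
            "frame": s.frames,
            "dist_um": s.dist_um,
            "dist_met": s.c_dist,
            "v_um_min": s.v_um_min,
            "v_norm": s.v_norm,
            "speed_met": s.c_speed,
            "cr": s.cr,
            "cr_met": s.c_conf,
        }
    )
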