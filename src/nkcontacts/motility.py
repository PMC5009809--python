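"""Per-track and per-FOV motility quantities.

All speeds are in μm/min (the field's customary unit for lymphocytes); time
stamps on tracks are in seconds, so finite differences are rescaled by 60.

Definitions
-----------
instantaneous speed
    v(t_i) = |r(t_i) - r(t_{i-1})| / (t_i - t_{i-1}), i >= 1.  The speed at
    the first frame is defined equal to the second frame's, which keeps the
    per-frame criterion series full-length.
confinement ratio
    CR(t_i) = |r(t_i) - r(t_0)| / L(t_i), the net displacement from the
    track start over the cumulative trace length; CR(t_0) := 1 by
    convention (a not-yet-moved cell is maximally straight).  CR lies in
    [0, 1] by the triangle inequality: 1 for ballistic motion, -> 0 for
    confined motion.
FOV-average speed
    V_FOV = mean over tracked cells of their mean instantaneous speed (a
    two-stage mean, so long and short tracks weigh equally).  By default the
    averaging base is the NK tracks: DCs are near-sessile and would drag an
    "all cells" average toward zero.  The cell-type set is configurable and
    recorded in the returned summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trackio import FieldOfView, Trajectory

__all__ = [
    "SpeedSeries",
    "ConfinementSeries",
    "FovSpeedSummary",
    "instantaneous_speed",
    "trace_length",
    "confinement_ratio",
    "mean_track_speed",
    "fov_average_speed",
    "normalized_speed",
]


@dataclass
class SpeedSeries:
    """Per-frame instantaneous speed for one track (μm/min).

    ``v_norm`` is the digitized/normalized speed used in criterion plots:
    0 exactly on frames where the speed criterion holds, v/V_FOV elsewhere.
    It is None until :func:`normalized_speed` fills it in.
    """

    frames: np.ndarray
    times_s: np.ndarray
    v_um_min: np.ndarray
    mean_um_min: float
    v_norm: np.ndarray | None = None


@dataclass
class ConfinementSeries:
    """Per-frame confinement ratio, trace length and net displacement."""

    frames: np.ndarray
    cr: np.ndarray
    trace_len_um: np.ndarray
    net_disp_um: np.ndarray


@dataclass
class FovSpeedSummary:
    """FOV-average speed and its per-track basis."""

    v_fov_um_min: float
    per_track_um_min: dict[str, float]
    n_tracks: int
    cell_types: tuple[str, ...]


def _require_points(track: Trajectory, n: int = 2) -> None:
    if track.n_points < n:
        raise ValueError(
            f"track {track.cell_id!r} has {track.n_points} point(s); >= {n} required"
        )


def _step_lengths(track: Trajectory) -> np.ndarray:
    return np.linalg.norm(np.diff(track.xyz, axis=0), axis=1)


def instantaneous_speed(track: Trajectory) -> SpeedSeries:
    """Finite-difference speed per frame, in μm/min; v(t_0) := v(t_1)."""
    _require_points(track)
    steps = _step_lengths(track)
    dt = np.diff(track.times_s)
    v = np.empty(track.n_points)
    v[1:] = steps / dt * 60.0
    v[0] = v[1]
    return SpeedSeries(
        frames=track.frames.copy(),
        times_s=track.times_s.copy(),
        v_um_min=v,
        mean_um_min=float(np.mean(v[1:])),
    )


def trace_length(track: Trajectory, upto_frame: int) -> float:
    """Cumulative 3D path length (μm) from the first frame through
    ``upto_frame`` (which must be a frame of the track)."""
    idx = np.nonzero(track.frames == upto_frame)[0]
    if len(idx) == 0:
        raise ValueError(f"frame {upto_frame} not in track {track.cell_id!r}")
    return float(np.sum(_step_lengths(track)[: idx[0]]))


def confinement_ratio(track: Trajectory) -> ConfinementSeries:
    """Full confinement-ratio series of a track (cumulative from start)."""
    _require_points(track)
    steps = _step_lengths(track)
    trace = np.concatenate(([0.0], np.cumsum(steps)))
    net = np.linalg.norm(track.xyz - track.xyz[0], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cr = np.where(trace > 0, net / np.where(trace > 0, trace, 1.0), 1.0)
    cr[0] = 1.0
    # guard against floating overshoot of the triangle-inequality bound
    np.clip(cr, 0.0, 1.0, out=cr)
    return ConfinementSeries(
        frames=track.frames.copy(), cr=cr, trace_len_um=trace, net_disp_um=net
    )


def mean_track_speed(track: Trajectory) -> float:
    """Arithmetic mean of instantaneous speeds over frames i >= 1 (μm/min)."""
    _require_points(track)
    steps = _step_lengths(track)
    dt = np.diff(track.times_s)
    return float(np.mean(steps / dt * 60.0))


def fov_average_speed(
    fov: FieldOfView, cell_types: frozenset[str] | set[str] = frozenset({"NK"})
) -> FovSpeedSummary:
    """Mean of per-track mean speeds over tracks of the given types.

    Iteration is in cell_id order, so the result is independent of the
    trajectory ordering inside the FOV.
    """
    eligible = sorted(
        (t for t in fov.trajectories if t.cell_type in cell_types and t.n_points >= 2),
        key=lambda t: t.cell_id,
    )
    if not eligible:
        raise ValueError(
            f"no eligible tracks of type {sorted(cell_types)} in FOV {fov.fov_id!r}"
        )
    per_track = {t.cell_id: mean_track_speed(t) for t in eligible}
    return FovSpeedSummary(
        v_fov_um_min=float(np.mean(list(per_track.values()))),
        per_track_um_min=per_track,
        n_tracks=len(per_track),
        cell_types=tuple(sorted(cell_types)),
    )


def normalized_speed(
    track: Trajectory, v_fov_um_min: float, alpha: float = 0.60
) -> SpeedSeries:
    """Speed series with the digitized normalized speed filled in.

    v_norm(t_i) = 0 where v(t_i) <= alpha * V_FOV (inclusive boundary:
    a cell at exactly the threshold fraction of the FOV average meets the
    criterion), else v(t_i)/V_FOV.  The zero-set of v_norm is therefore
    exactly the set of frames where the speed criterion holds.
    """
    if v_fov_um_min <= 0:
        raise ValueError("v_fov_um_min must be > 0")
    series = instantaneous_speed(track)
    v = series.v_um_min
    series.v_norm = np.where(v <= alpha * v_fov_um_min, 0.0, v / v_fov_um_min)
    return series
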