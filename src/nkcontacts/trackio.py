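"""Trajectory data model and the track-table CSV format.

The on-disk format is a plain UTF-8 CSV with one row per cell per frame and
the fixed header::

    fov_id,condition,cell_id,cell_type,frame,time_s,x_um,y_um,z_um

Coordinates are centroid positions in micrometres (3D, physical units; pixel
units are not accepted).  Rows are grouped into :class:`Trajectory` objects
(one tracked cell) and :class:`FieldOfView` objects (one imaged volume /
movie with a shared frame clock).  This mirrors the exports of common cell
tracking software (TrackMate, Imaris/Volocity spot tables) closely enough
that real exports only need column renaming.

Missing frames (tracking gaps) are tolerated at read time; they are
reported by :func:`validate_fov` as informational findings and handled
downstream by the interaction detector, which never bridges a gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TRACK_COLUMNS",
    "CELL_TYPES",
    "TrackFormatError",
    "TrackValidationError",
    "TrackPoint",
    "Trajectory",
    "FieldOfView",
    "DetectorConfig",
    "Finding",
    "read_tracks",
    "write_tracks",
    "validate_fov",
    "fovs_equal",
]

TRACK_COLUMNS = [
    "fov_id",
    "condition",
    "cell_id",
    "cell_type",
    "frame",
    "time_s",
    "x_um",
    "y_um",
    "z_um",
]

CELL_TYPES = {"NK", "DC", "T"}

#: serialization precision for coordinates/times; round-trips are value-stable
_FLOAT_FORMAT = "%.6f"


class TrackFormatError(ValueError):
    """The file does not conform to the track-table schema."""


class TrackValidationError(ValueError):
    """The file parses but violates a trajectory invariant."""


@dataclass(frozen=True)
class TrackPoint:
    """One observation of one cell: frame index, time and 3D position (μm)."""

    frame: int
    time_s: float
    x_um: float
    y_um: float
    z_um: float


@dataclass
class Trajectory:
    """One tracked cell: ordered observations plus identity and type.

    ``frames``/``times_s`` are 1D arrays, ``xyz`` is ``(n, 3)`` in μm.
    Construction is lenient (so noisy pipelines can build partial tracks);
    strict invariants (>= 2 points, strictly increasing frames and times,
    finite coordinates) are enforced by :func:`validate_fov`.
    """

    cell_id: str
    cell_type: str
    frames: np.ndarray
    times_s: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be (n, 3), got {self.xyz.shape}")
        if not (len(self.frames) == len(self.times_s) == len(self.xyz)):
            raise ValueError("frames, times_s and xyz must have equal length")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def points(self) -> list[TrackPoint]:
        return [
            TrackPoint(int(f), float(t), float(x), float(y), float(z))
            for f, t, (x, y, z) in zip(self.frames, self.times_s, self.xyz)
        ]

    @classmethod
    def from_points(
        cls, cell_id: str, cell_type: str, points: Iterable[TrackPoint]
    ) -> "Trajectory":
        pts = list(points)
        return cls(
            cell_id=cell_id,
            cell_type=cell_type,
            frames=np.array([p.frame for p in pts], dtype=np.int64),
            times_s=np.array([p.time_s for p in pts], dtype=float),
            xyz=np.array([[p.x_um, p.y_um, p.z_um] for p in pts], dtype=float)
            if pts
            else np.empty((0, 3)),
        )


@dataclass
class FieldOfView:
    """One imaged volume: co-registered trajectories on a shared frame clock."""

    fov_id: str
    condition: str
    frame_interval_s: float
    trajectories: list[Trajectory] = field(default_factory=list)

    def by_type(self, cell_type: str) -> list[Trajectory]:
        return [t for t in self.trajectories if t.cell_type == cell_type]

    def get(self, cell_id: str) -> Trajectory:
        for t in self.trajectories:
            if t.cell_id == cell_id:
                return t
        raise KeyError(f"no trajectory {cell_id!r} in FOV {self.fov_id!r}")

    @property
    def nk_tracks(self) -> list[Trajectory]:
        return self.by_type("NK")

    @property
    def dc_tracks(self) -> list[Trajectory]:
        return self.by_type("DC")


@dataclass
class DetectorConfig:
    """Thresholds of the three-criterion interaction detector.

    distance_threshold_um
        d: largest NK-DC centroid distance (μm) still counted as proximity
        (inclusive).
    speed_fraction
        α: an NK frame passes the speed criterion when its instantaneous
        speed is <= α times the FOV-average speed.
    cr_tolerance
        ε_CR: slack on the frame-to-frame confinement-ratio comparison; the
        confinement criterion holds when CR(t_i) <= CR(t_{i-1}) + ε_CR.
    long_threshold_s / touch_and_go_s
        duration class boundaries: long iff duration >= long_threshold_s,
        touch-and-go iff duration < touch_and_go_s.
    tolerance_enabled
        absorb an isolated interior frame at which exactly one criterion
        fails into the surrounding event.
    """

    distance_threshold_um: float = 25.0
    speed_fraction: float = 0.60
    cr_tolerance: float = 0.01
    long_threshold_s: float = 900.0
    touch_and_go_s: float = 5.0
    tolerance_enabled: bool = True

    def __post_init__(self) -> None:
        if self.distance_threshold_um <= 0:
            raise ValueError("distance_threshold_um must be > 0")
        if not 0 < self.speed_fraction < 1:
            raise ValueError("speed_fraction must be in (0, 1)")
        if self.cr_tolerance <= 0:
            raise ValueError("cr_tolerance must be > 0")
        if self.long_threshold_s <= 0 or self.touch_and_go_s <= 0:
            raise ValueError("duration thresholds must be > 0")
        if self.touch_and_go_s >= self.long_threshold_s:
            raise ValueError("touch_and_go_s must be < long_threshold_s")

    def to_dict(self) -> dict:
        return {
            "distance_threshold_um": self.distance_threshold_um,
            "speed_fraction": self.speed_fraction,
            "cr_tolerance": self.cr_tolerance,
            "long_threshold_s": self.long_threshold_s,
            "touch_and_go_s": self.touch_and_go_s,
            "tolerance_enabled": self.tolerance_enabled,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown detector config fields: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class Finding:
    """One validation finding. severity is 'error' or 'info'."""

    severity: str
    fov_id: str
    cell_id: str | None
    frame: int | None
    message: str

    def to_dict(self) -> dict:
        return {
            "severity": self.severity,
            "fov_id": self.fov_id,
            "cell_id": self.cell_id,
            "frame": self.frame,
            "message": self.message,
        }


def _to_dataframe(fovs: Sequence[FieldOfView]) -> pd.DataFrame:
    rows = []
    for fov in sorted(fovs, key=lambda f: f.fov_id):
        for traj in sorted(fov.trajectories, key=lambda t: t.cell_id):
            order = np.argsort(traj.frames, kind="stable")
            for i in order:
                rows.append(
                    (
                        fov.fov_id,
                        fov.condition,
                        traj.cell_id,
                        traj.cell_type,
                        int(traj.frames[i]),
                        float(traj.times_s[i]),
                        float(traj.xyz[i, 0]),
                        float(traj.xyz[i, 1]),
                        float(traj.xyz[i, 2]),
                    )
                )
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def write_tracks(fovs: Sequence[FieldOfView], path: str | Path) -> None:
    """Write fields of view to the track-table CSV.

    Row order is deterministic (fov_id, cell_id, frame) and floats are
    serialized at fixed precision so that write -> read round-trips are
    value-stable.  An empty FOV list produces a header-only file.
    """
    df = _to_dataframe(fovs)
    df.to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_tracks(path: str | Path) -> list[FieldOfView]:
    """Read a track-table CSV into fields of view.

    Trajectories are grouped by ``(fov_id, cell_id)`` and sorted by frame.
    ``frame_interval_s`` of each FOV is inferred as the median inter-frame
    time gap over all its trajectories (robust to dropped frames and to row
    order in the file).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    header = list(pd.read_csv(path, nrows=0).columns)
    missing = [c for c in TRACK_COLUMNS if c not in header]
    if missing:
        raise TrackFormatError(f"missing required column(s): {missing}")
    unknown = [c for c in header if c not in TRACK_COLUMNS]
    if unknown:
        raise TrackFormatError(f"unknown column(s): {unknown}")

    df = pd.read_csv(
        path, dtype={"fov_id": str, "condition": str, "cell_id": str, "cell_type": str}
    )
    for col in ("frame", "time_s", "x_um", "y_um", "z_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise TrackFormatError(
                f"non-numeric value in column {col!r} at file row {row}"
            )
        df[col] = coerced
    if df[["frame", "time_s", "x_um", "y_um", "z_um"]].isna().any().any():
        col = df[["frame", "time_s", "x_um", "y_um", "z_um"]].isna().any().idxmax()
        raise TrackFormatError(f"missing value in column {col!r}")

    bad_types = set(df["cell_type"].unique()) - CELL_TYPES
    if bad_types:
        raise TrackFormatError(
            f"unknown cell_type value(s) {sorted(bad_types)}; expected {sorted(CELL_TYPES)}"
        )

    fovs: list[FieldOfView] = []
    for fov_id, fdf in df.groupby("fov_id", sort=True):
        conditions = fdf["condition"].unique()
        if len(conditions) > 1:
            raise TrackFormatError(
                f"FOV {fov_id!r} has inconsistent condition labels: {sorted(conditions)}"
            )
        trajectories = []
        gaps = []
        for cell_id, cdf in fdf.groupby("cell_id", sort=True):
            types = cdf["cell_type"].unique()
            if len(types) > 1:
                raise TrackFormatError(
                    f"cell {cell_id!r} in FOV {fov_id!r} has multiple cell_type values"
                )
            cdf = cdf.sort_values("frame", kind="stable")
            times = cdf["time_s"].to_numpy(dtype=float)
            if len(times) > 1 and not np.all(np.diff(times) > 0):
                raise TrackValidationError(
                    f"non-monotonic time within cell {cell_id!r} in FOV {fov_id!r}"
                )
            trajectories.append(
                Trajectory(
                    cell_id=str(cell_id),
                    cell_type=str(types[0]),
                    frames=cdf["frame"].to_numpy(dtype=np.int64),
                    times_s=times,
                    xyz=cdf[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
                )
            )
            if len(times) > 1:
                gaps.append(np.diff(times))
        interval = float(np.median(np.concatenate(gaps))) if gaps else float("nan")
        fovs.append(
            FieldOfView(
                fov_id=str(fov_id),
                condition=str(conditions[0]),
                frame_interval_s=interval,
                trajectories=trajectories,
            )
        )
    return fovs


def validate_fov(fov: FieldOfView) -> list[Finding]:
    """Check all trajectory/FOV invariants; return findings, raise nothing.

    An empty list means the FOV is well formed.  Tracking gaps (missing
    frames) yield *informational* findings only.
    """
    findings: list[Finding] = []

    def err(cell_id, frame, msg):
        findings.append(Finding("error", fov.fov_id, cell_id, frame, msg))

    def info(cell_id, frame, msg):
        findings.append(Finding("info", fov.fov_id, cell_id, frame, msg))

    if not np.isfinite(fov.frame_interval_s) or fov.frame_interval_s <= 0:
        err(None, None, f"frame_interval_s must be > 0, got {fov.frame_interval_s}")
        return findings

    seen: set[str] = set()
    for traj in fov.trajectories:
        cid = traj.cell_id
        if cid in seen:
            err(cid, None, "duplicate cell_id within field of view")
        seen.add(cid)
        if traj.n_points < 2:
            err(cid, None, "fewer than 2 points")
            continue
        dup = traj.frames[:-1][np.diff(traj.frames) == 0]
        for f in np.unique(dup):
            err(cid, int(f), f"duplicate frame {int(f)}")
        if np.any(np.diff(traj.frames) < 0):
            err(cid, None, "frames not strictly increasing")
        if np.any(np.diff(traj.times_s) <= 0):
            err(cid, None, "times not strictly increasing")
        if np.any(traj.times_s < 0) or not np.all(np.isfinite(traj.times_s)):
            err(cid, None, "times must be finite and non-negative")
        if not np.all(np.isfinite(traj.xyz)):
            err(cid, None, "non-finite coordinate")
        # shared-clock consistency: every time gap an integer multiple of the
        # nominal interval (5% relative tolerance)
        dt = np.diff(traj.times_s)
        if len(dt) and np.all(dt > 0):
            mult = dt / fov.frame_interval_s
            off = np.abs(mult - np.round(mult))
            if np.any(off > 0.05):
                i = int(np.argmax(off))
                err(
                    cid,
                    int(traj.frames[i + 1]),
                    "inter-frame gap is not a multiple of frame_interval_s",
                )
            for i in np.nonzero(np.round(mult) > 1)[0]:
                info(
                    cid,
                    int(traj.frames[i + 1]),
                    f"gap of {int(round(mult[i])) - 1} missing frame(s)",
                )
    return findings


def fovs_equal(
    a: Sequence[FieldOfView], b: Sequence[FieldOfView], atol: float = 1e-6
) -> bool:
    """Field-by-field equality of two FOV collections within serialization
    precision (used to assert read-write round-trip identity)."""
    if len(a) != len(b):
        return False
    for fa, fb in zip(
        sorted(a, key=lambda f: f.fov_id), sorted(b, key=lambda f: f.fov_id)
    ):
        if fa.fov_id != fb.fov_id or fa.condition != fb.condition:
            return False
        if not np.isclose(fa.frame_interval_s, fb.frame_interval_s, atol=atol):
            return False
        ta = sorted(fa.trajectories, key=lambda t: t.cell_id)
        tb = sorted(fb.trajectories, key=lambda t: t.cell_id)
        if len(ta) != len(tb):
            return False
        for x, y in zip(ta, tb):
            if x.cell_id != y.cell_id or x.cell_type != y.cell_type:
                return False
            if not np.array_equal(x.frames, y.frames):
                return False
            if not np.allclose(x.times_s, y.times_s, atol=atol):
                return False
            if not np.allclose(x.xyz, y.xyz, atol=atol):
                return False
    return True
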