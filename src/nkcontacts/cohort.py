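"""Population-level statistics built on detected interaction events.

The readouts mirror the standard imaging-cohort summaries: the fraction of
tracked NK cells that interact with any DC, the fraction of *interacting*
cells whose longest contact is a long interaction (>= 15 min), duration and
per-cell 3D velocity distributions, and unpaired two-tailed t-tests between
conditions.  All dispersion is reported as mean ± SEM (SEM = sd/sqrt(n)
with the n-1 denominator for sd).

A cell's interaction class is decided by its LONGEST event: "cells showing
long interaction times" is a per-cell, not per-event, statement, so a cell
with one long and many short contacts counts once as a long-interacting
cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .detection import InteractionEvent
from .motility import mean_track_speed
from .trackio import FieldOfView

__all__ = [
    "CohortSummary",
    "DurationSummary",
    "LongFraction",
    "ComparisonResult",
    "interacting_fraction",
    "long_fraction",
    "duration_summary",
    "velocity_summary",
    "compare_conditions",
    "summarize_cohort",
]


def _sem(values: np.ndarray) -> float | None:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return None
    return float(np.std(values, ddof=1) / np.sqrt(len(values)))


def interacting_fraction(
    events: list[InteractionEvent], fov: FieldOfView
) -> float:
    """Percentage of tracked NK cells with at least one event in this FOV."""
    nk_ids = {t.cell_id for t in fov.nk_tracks}
    if not nk_ids:
        raise ValueError(f"FOV {fov.fov_id!r} has no NK tracks")
    interacting = {e.nk_id for e in events if e.fov_id == fov.fov_id} & nk_ids
    return 100.0 * len(interacting) / len(nk_ids)


@dataclass(frozen=True)
class LongFraction:
    """Percentage of interacting cells whose longest event is long.

    ``defined`` is False when there are no interacting cells (the value is
    then reported as 0 but carries no information).
    """

    value_pct: float
    n_interacting: int
    n_long: int
    defined: bool


def _longest_per_cell(events: list[InteractionEvent]) -> dict[tuple[str, str], InteractionEvent]:
    longest: dict[tuple[str, str], InteractionEvent] = {}
    for e in events:
        key = (e.fov_id, e.nk_id)
        if key not in longest or e.duration_s > longest[key].duration_s:
            longest[key] = e
    return longest


def long_fraction(events: list[InteractionEvent]) -> LongFraction:
    """Fraction of interacting NK cells whose longest contact is long."""
    longest = _longest_per_cell(events)
    if not longest:
        return LongFraction(0.0, 0, 0, defined=False)
    n_long = sum(1 for e in longest.values() if e.event_class == "long")
    return LongFraction(
        100.0 * n_long / len(longest), len(longest), n_long, defined=True
    )


@dataclass(frozen=True)
class DurationSummary:
    mean_s: float | None
    sem_s: float | None
    n: int
    class_counts: dict[str, int]

    @property
    def is_empty(self) -> bool:
        return self.n == 0


def duration_summary(events: list[InteractionEvent]) -> DurationSummary:
    """Mean ± SEM of event durations and counts per class."""
    counts = {"touch_and_go": 0, "intermediate": 0, "long": 0}
    for e in events:
        counts[e.event_class] += 1
    if not events:
        return DurationSummary(None, None, 0, counts)
    durations = np.array([e.duration_s for e in events], dtype=float)
    return DurationSummary(
        mean_s=float(np.mean(durations)),
        sem_s=_sem(durations),
        n=len(events),
        class_counts=counts,
    )


def velocity_summary(
    fov: FieldOfView, interacting_ids: set[str]
) -> dict[str, float]:
    """Per-cell mean 3D speed (μm/min) of the given interacting NK cells."""
    nk_by_id = {t.cell_id: t for t in fov.nk_tracks}
    unknown = set(interacting_ids) - set(nk_by_id)
    if unknown:
        raise ValueError(f"unknown NK id(s) in FOV {fov.fov_id!r}: {sorted(unknown)}")
    return {cid: mean_track_speed(nk_by_id[cid]) for cid in sorted(interacting_ids)}


@dataclass(frozen=True)
class ComparisonResult:
    """Unpaired two-tailed equal-variance t-test plus descriptives."""

    t: float
    p: float
    mean_a: float
    sem_a: float | None
    mean_b: float
    sem_b: float | None
    n_a: int
    n_b: int
    degenerate: bool  # zero pooled variance; t/p are not meaningful

    def to_dict(self) -> dict:
        return {
            "test": "two-tailed unpaired Student t (equal variance)",
            "t": None if np.isnan(self.t) else self.t,
            "p": None if np.isnan(self.p) else self.p,
            "mean_a": self.mean_a,
            "sem_a": self.sem_a,
            "mean_b": self.mean_b,
            "sem_b": self.sem_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "degenerate": self.degenerate,
        }


def compare_conditions(a, b) -> ComparisonResult:
    """Compare two samples with an unpaired two-tailed Student t-test.

    A zero pooled variance (both samples constant) is flagged rather than
    raised; t and p are NaN in that case.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    pooled_var = (
        (len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)
    ) / (len(a) + len(b) - 2)
    if pooled_var == 0:
        if np.mean(a) == np.mean(b):
            # identical constants: no difference, conventionally t=0, p=1
            return ComparisonResult(
                0.0, 1.0, float(np.mean(a)), _sem(a), float(np.mean(b)), _sem(b),
                len(a), len(b), degenerate=True,
            )
        return ComparisonResult(
            float("nan"), float("nan"), float(np.mean(a)), _sem(a),
            float(np.mean(b)), _sem(b), len(a), len(b), degenerate=True,
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        float(t), float(p), float(np.mean(a)), _sem(a), float(np.mean(b)), _sem(b),
        len(a), len(b), degenerate=False,
    )


@dataclass
class CohortSummary:
    """All per-condition readouts, JSON-serializable via :meth:`to_dict`."""

    condition: str
    n_nk_tracked: int
    n_nk_interacting: int
    interacting_fraction_pct: float
    n_long_cells: int
    long_fraction_of_interacting_pct: float
    long_fraction_of_tracked_pct: float
    durations_s: list[float] = field(default_factory=list)
    velocities_um_min: list[float] = field(default_factory=list)
    duration_mean_s: float | None = None
    duration_sem_s: float | None = None
    velocity_mean_um_min: float | None = None
    velocity_sem_um_min: float | None = None
    class_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_nk_tracked": self.n_nk_tracked,
            "n_nk_interacting": self.n_nk_interacting,
            "interacting_fraction_pct": self.interacting_fraction_pct,
            "n_long_cells": self.n_long_cells,
            "long_fraction_of_interacting_pct": self.long_fraction_of_interacting_pct,
            "long_fraction_of_tracked_pct": self.long_fraction_of_tracked_pct,
            "duration_mean_s": self.duration_mean_s,
            "duration_sem_s": self.duration_sem_s,
            "velocity_mean_um_min": self.velocity_mean_um_min,
            "velocity_sem_um_min": self.velocity_sem_um_min,
            "event_class_counts": self.class_counts,
            "durations_s": self.durations_s,
            "velocities_um_min": self.velocities_um_min,
        }


def summarize_cohort(
    fovs: list[FieldOfView], events: list[InteractionEvent], condition: str
) -> CohortSummary:
    """Aggregate events from all FOVs of one condition into a summary.

    Cells are keyed by (fov_id, cell_id), so identical cell ids in
    different FOVs never collide.  Velocities are the per-cell mean 3D
    speeds of the interacting NK cells.
    """
    fovs = [f for f in fovs if f.condition == condition]
    if not fovs:
        raise ValueError(f"no FOV with condition {condition!r}")
    fov_ids = {f.fov_id for f in fovs}
    events = [e for e in events if e.fov_id in fov_ids]

    n_tracked = sum(len(f.nk_tracks) for f in fovs)
    if n_tracked == 0:
        raise ValueError(f"condition {condition!r} has no NK tracks")
    longest = _longest_per_cell(events)
    n_interacting = len(longest)
    n_long = sum(1 for e in longest.values() if e.event_class == "long")

    velocities: list[float] = []
    for fov in fovs:
        ids = {e.nk_id for e in events if e.fov_id == fov.fov_id}
        velocities.extend(velocity_summary(fov, ids).values())

    dsum = duration_summary(events)
    velocities_arr = np.asarray(velocities, dtype=float)
    return CohortSummary(
        condition=condition,
        n_nk_tracked=n_tracked,
        n_nk_interacting=n_interacting,
        interacting_fraction_pct=100.0 * n_interacting / n_tracked,
        n_long_cells=n_long,
        long_fraction_of_interacting_pct=(
            100.0 * n_long / n_interacting if n_interacting else 0.0
        ),
        long_fraction_of_tracked_pct=100.0 * n_long / n_tracked,
        durations_s=[e.duration_s for e in events],
        velocities_um_min=velocities,
        duration_mean_s=dsum.mean_s,
        duration_sem_s=dsum.sem_s,
        velocity_mean_um_min=(
            float(np.mean(velocities_arr)) if len(velocities_arr) else None
        ),
        velocity_sem_um_min=_sem(velocities_arr),
        class_counts=dsum.class_counts,
    )
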