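"""End-to-end validation battery: threshold-boundary scans and recovery.

Every quantity here is recomputed from scratch by running the pipeline —
simulating tracks, detecting events, classifying and summarizing — never
read from a table.  The scans locate the detector's operating boundaries
(duration class cut-offs, distance and speed thresholds) by sweeping
planted inputs across a grid; the recovery and null checks exercise the
simulator-detector loop.
"""

from __future__ import annotations

import numpy as np

from .detection import detect_all, speed_criterion
from .simulate import Episode, SimulationConfig, recovery_experiment, simulate_fov
from .trackio import DetectorConfig, FieldOfView, Trajectory

__all__ = [
    "planted_pair_fov",
    "scan_long_duration_boundary",
    "scan_touch_and_go_boundary",
    "scan_distance_threshold",
    "scan_speed_fraction",
    "null_specificity",
    "quick_recovery_check",
    "run_validation",
]


def planted_pair_fov(
    seed: int, k_frames: int, frame_interval_s: float
) -> FieldOfView:
    """One NK and one DC with a planted fully-qualifying contact run of
    exactly ``k_frames`` frames, noiseless."""
    config = SimulationConfig(
        seed=seed,
        n_frames=k_frames + 6,
        frame_interval_s=frame_interval_s,
        volume_um=(150.0, 150.0, 60.0),
        n_nk=1,
        n_dc=1,
        episodes=(Episode("NK000", "DC000", start_frame=2, n_frames=k_frames),),
    )
    fov, _ = simulate_fov(config)
    return fov


def _detect_planted_duration(
    seed: int, k_frames: int, frame_interval_s: float, config: DetectorConfig
) -> tuple[float, str]:
    """Detected duration and class of a planted k-frame contact run."""
    fov = planted_pair_fov(seed, k_frames, frame_interval_s)
    events = detect_all(fov, config)
    if not events:
        return 0.0, "none"
    longest = max(events, key=lambda e: e.duration_s)
    return longest.duration_s, longest.event_class


def scan_long_duration_boundary(
    seed: int = 0, config: DetectorConfig | None = None
) -> dict:
    """Smallest planted contact duration classified 'long'.

    Planted fully-qualifying runs of 30 s .. 1800 s in 30 s steps at a
    30 s frame interval, run through detection and classification.
    """
    config = config or DetectorConfig()
    interval = 30.0
    durations = [interval * k for k in range(1, 61)]
    smallest = None
    for dur in durations:
        k = int(round(dur / interval))
        _, cls = _detect_planted_duration(seed + k, k, interval, config)
        if cls == "long" and smallest is None:
            smallest = dur
    return {"value": smallest, "n": len(durations), "units": "s"}


def scan_touch_and_go_boundary(
    seed: int = 0, config: DetectorConfig | None = None
) -> dict:
    """Smallest planted contact duration NOT classified touch-and-go,
    scanning 1 s .. 20 s planted runs at a 1 s frame interval."""
    config = config or DetectorConfig()
    interval = 1.0
    durations = [interval * k for k in range(1, 21)]
    smallest = None
    for dur in durations:
        k = int(round(dur / interval))
        _, cls = _detect_planted_duration(seed + 1000 + k, k, interval, config)
        if cls not in ("touch_and_go", "none") and smallest is None:
            smallest = dur
    return {"value": smallest, "n": len(durations), "units": "s"}


def _stationary_pair(separation_um: float, n_frames: int = 4) -> tuple[Trajectory, Trajectory]:
    frames = np.arange(n_frames)
    times = frames * 30.0
    nk = Trajectory(
        "NK000", "NK", frames, times, np.zeros((n_frames, 3))
    )
    dc_xyz = np.zeros((n_frames, 3))
    dc_xyz[:, 0] = separation_um
    dc = Trajectory("DC000", "DC", frames, times, dc_xyz)
    return nk, dc


def scan_distance_threshold(config: DetectorConfig | None = None) -> dict:
    """Largest constant NK-DC separation (integer μm grid, 1..60) at which
    the per-frame distance criterion is satisfied."""
    from .detection import pair_distance

    config = config or DetectorConfig()
    largest = None
    for sep in range(1, 61):
        nk, dc = _stationary_pair(float(sep))
        series = pair_distance(nk, dc, config.distance_threshold_um)
        if series.met.all():
            largest = sep
    return {"value": largest, "n": 60, "units": "um"}


def scan_speed_fraction(config: DetectorConfig | None = None) -> dict:
    """Largest test-cell speed, as an integer percent of a fixed FOV-average
    speed of 10 μm/min, whose frames satisfy the speed criterion."""
    config = config or DetectorConfig()
    v_fov = 10.0
    largest = None
    for k in range(1, 101):
        v = np.full(5, k / 100 * v_fov)
        if speed_criterion(v, v_fov, config.speed_fraction).all():
            largest = k
    return {"value": largest, "n": 100, "units": "percent"}


def null_specificity(
    seed: int = 0,
    n_reps: int = 50,
    config: DetectorConfig | None = None,
) -> dict:
    """Total events detected across no-contact replicates in which every NK
    cell is kept at least 2d away from every DC."""
    detector = config or DetectorConfig()
    total = 0
    for rep in range(n_reps):
        sim = SimulationConfig(
            seed=int(
                np.random.SeedSequence([seed, 523, rep]).generate_state(1)[0] % 2**31
            ),
            n_frames=40,
            n_nk=20,
            n_dc=5,
            jitter_sd_um=0.5,
            dc_exclusion_um=2 * detector.distance_threshold_um,
        )
        fov, _ = simulate_fov(sim)
        total += len(detect_all(fov, detector))
    return {"value": total, "n": n_reps}


def quick_recovery_check(
    seed: int = 0,
    planted_fraction: float = 0.45,
    n_reps: int = 5,
    n_nk: int = 40,
    config: DetectorConfig | None = None,
) -> dict:
    """Small simulate-detect-recover loop; returns planted and recovered
    interacting fractions pooled over replicates."""
    detector = config or DetectorConfig()
    sim = SimulationConfig(
        seed=seed,
        n_nk=n_nk,
        n_dc=8,
        jitter_sd_um=0.5,
        planted_fraction=planted_fraction,
    )
    report = recovery_experiment(sim, detector, n_reps)
    pooled_n = sum(r["n_nk"] for r in report.rows)
    return {
        "planted_fraction": report.pooled("planted_n") / pooled_n,
        "recovered_fraction": report.pooled("recovered_n") / pooled_n,
        "median_abs_duration_error_frames": (
            float(np.median(np.abs(report.duration_errors_frames)))
            if report.duration_errors_frames
            else None
        ),
        "n": pooled_n,
    }


def run_validation(seed: int = 0, config: DetectorConfig | None = None) -> dict:
    """Run the full battery and report each check's observed value,
    expected relation and pass/fail.

    The battery runs with the *given* detector configuration but always
    compares the boundary scans against the published reference thresholds
    (the DetectorConfig defaults), so an overridden threshold is reported
    and fails the corresponding check — a deliberate negative control.
    """
    detector = config or DetectorConfig()
    reference = DetectorConfig()
    checks = []

    long_scan = scan_long_duration_boundary(seed, detector)
    checks.append(
        {
            "check": "smallest planted duration classified long (s)",
            "observed": long_scan["value"],
            "expected": reference.long_threshold_s,
            "relation": "eq",
            "passed": long_scan["value"] == reference.long_threshold_s,
        }
    )
    tng_scan = scan_touch_and_go_boundary(seed, detector)
    checks.append(
        {
            "check": "smallest planted duration not touch-and-go (s)",
            "observed": tng_scan["value"],
            "expected": reference.touch_and_go_s,
            "relation": "eq",
            "passed": tng_scan["value"] == reference.touch_and_go_s,
        }
    )
    dist_scan = scan_distance_threshold(detector)
    checks.append(
        {
            "check": "largest separation meeting the distance criterion (um)",
            "observed": dist_scan["value"],
            "expected": reference.distance_threshold_um,
            "relation": "eq",
            "passed": dist_scan["value"] == reference.distance_threshold_um,
        }
    )
    speed_scan = scan_speed_fraction(detector)
    checks.append(
        {
            "check": "largest speed percent meeting the speed criterion",
            "observed": speed_scan["value"],
            "expected": round(100 * reference.speed_fraction),
            "relation": "eq",
            "passed": speed_scan["value"] == round(100 * reference.speed_fraction),
        }
    )
    null = null_specificity(seed, n_reps=10, config=detector)
    checks.append(
        {
            "check": "events detected with >= 2d NK-DC separation",
            "observed": null["value"],
            "expected": 0,
            "relation": "eq",
            "passed": null["value"] == 0,
        }
    )
    rec = quick_recovery_check(seed, config=detector)
    tol = 0.05
    checks.append(
        {
            "check": "recovered vs planted interacting fraction",
            "observed": rec["recovered_fraction"],
            "expected": rec["planted_fraction"],
            "relation": f"abs diff <= {tol}",
            "passed": abs(rec["recovered_fraction"] - rec["planted_fraction"]) <= tol,
        }
    )
    return {
        "seed": seed,
        "detector": detector.to_dict(),
        "checks": checks,
        "all_passed": all(c["passed"] for c in checks),
    }
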