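#!/usr/bin/env python
"""Cohort statistics and the between-condition comparison.

Consumes the event tables from 02_detect_interactions.py and the tracks
from 01_simulate_cohorts.py.  Reports, per condition: the fraction of
tracked NK cells interacting with DCs, the fraction of interacting cells
whose longest contact is long (>= 15 min), contact-duration mean ± SEM,
and the per-cell 3D velocity distribution of interacting cells.  Compares
the conditions with two-tailed unpaired t-tests and checks the recovered
fractions against the planted ground truth.

Writes results/cohort_statistics.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from nkcontacts.cohort import compare_conditions, summarize_cohort
from nkcontacts.detection import InteractionEvent
from nkcontacts.trackio import read_tracks

RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_events(path: Path) -> list[InteractionEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        InteractionEvent(
            fov_id=r["fov_id"],
            nk_id=r["nk_id"],
            dc_id=r["dc_id"],
            start_frame=int(r["start_frame"]),
            end_frame=int(r["end_frame"]),
            n_frames=int(r["n_frames"]),
            duration_s=float(r["duration_s"]),
            n_tolerated_frames=int(r["n_tolerated_frames"]),
            event_class=r["class"],
        )
        for r in df.to_dict("records")
    ]


def main() -> None:
    out = {}
    summaries = {}
    for name in ("steady_state", "LPS"):
        tracks_path = RESULTS / f"tracks_{name}.csv"
        events_path = RESULTS / f"events_{name}.tsv"
        if not tracks_path.exists() or not events_path.exists():
            sys.exit("inputs missing - run analysis scripts 01 and 02 first")
        fovs = read_tracks(tracks_path)
        events = load_events(events_path)
        summary = summarize_cohort(fovs, events, name)
        summaries[name] = summary
        gt = pd.read_csv(RESULTS / f"ground_truth_{name}.tsv", sep="\t")
        planted_cells = gt.groupby(["fov_id", "nk_id"]).size().shape[0]
        out[name] = {
            **summary.to_dict(),
            "planted_interacting_cells": int(planted_cells),
        }
        print(
            f"{name}: {summary.interacting_fraction_pct:.1f}% of "
            f"{summary.n_nk_tracked} NK cells interacting "
            f"(planted {100 * planted_cells / summary.n_nk_tracked:.1f}%), "
            f"{summary.long_fraction_of_interacting_pct:.1f}% of interacting "
            f"cells in long contacts, mean contact "
            f"{(summary.duration_mean_s or 0) / 60:.1f} min"
        )

    ss, lps = summaries["steady_state"], summaries["LPS"]
    velocity_test = compare_conditions(ss.velocities_um_min, lps.velocities_um_min)
    duration_test = compare_conditions(ss.durations_s, lps.durations_s)
    out["comparisons"] = {
        "velocities_steady_vs_lps": velocity_test.to_dict(),
        "durations_steady_vs_lps": duration_test.to_dict(),
    }
    print(
        f"interacting-cell 3D velocity, steady vs LPS: "
        f"{velocity_test.mean_a:.2f} vs {velocity_test.mean_b:.2f} μm/min "
        f"(t = {velocity_test.t:.2f}, p = {velocity_test.p:.3f})"
    )
    print(
        f"contact duration, steady vs LPS: {duration_test.mean_a:.0f} vs "
        f"{duration_test.mean_b:.0f} s (t = {duration_test.t:.2f}, "
        f"p = {duration_test.p:.2e})"
    )

    path = RESULTS / "cohort_statistics.json"
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"-> {path}")


if __name__ == "__main__":
    main()
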