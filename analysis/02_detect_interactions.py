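#!/usr/bin/env python
"""Detect NK-DC interaction events in the simulated cohorts.

Reads results/tracks_<condition>.csv (run 01_simulate_cohorts.py first),
applies the three-criterion detector with the published parameters
(d <= 25 μm, v <= 60% of the FOV average, non-increasing confinement
ratio, single-frame/single-criterion tolerance) and writes one events
table per condition plus a combined table.
"""

import sys
from pathlib import Path

from nkcontacts.detection import detect_all, events_to_frame
from nkcontacts.trackio import DetectorConfig, read_tracks

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    detector = DetectorConfig()
    frames = []
    for name in ("steady_state", "LPS"):
        tracks_path = RESULTS / f"tracks_{name}.csv"
        if not tracks_path.exists():
            sys.exit(f"{tracks_path} missing - run analysis/01_simulate_cohorts.py")
        fovs = read_tracks(tracks_path)
        events = []
        for fov in fovs:
            events.extend(detect_all(fov, detector))
        table = events_to_frame(events, {f.fov_id: f.condition for f in fovs})
        out = RESULTS / f"events_{name}.tsv"
        table.to_csv(out, sep="\t", index=False, float_format="%.6f")
        by_class = table["class"].value_counts().to_dict()
        print(
            f"{name}: {len(table)} events over {len(fovs)} FOVs "
            f"(classes: {by_class}) -> {out}"
        )
        frames.append(table)

    import pandas as pd

    pd.concat(frames).to_csv(
        RESULTS / "events_all.tsv", sep="\t", index=False, float_format="%.6f"
    )


if __name__ == "__main__":
    main()
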