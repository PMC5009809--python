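#!/usr/bin/env python
"""Simulate the two imaging cohorts the downstream analysis compares.

Steady state: ~45% of NK cells take (mostly short) DC contacts and ~1% of
interacting cells hold a long (>= 15 min) contact.  Inflammation (LPS):
~52% interacting and ~12% of interacting cells in long contacts.  Three
fields of view per condition, 50 NK + 10 DC each, 30 s frames, 30 min
movies, 0.5 μm localization jitter.

Writes results/tracks_<condition>.csv and ground_truth_<condition>.tsv.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from nkcontacts.simulate import SimulationConfig, simulate_cohort
from nkcontacts.trackio import write_tracks

RESULTS = Path(__file__).resolve().parent.parent / "results"

CONDITIONS = {
    "steady_state": SimulationConfig(
        seed=11,
        n_fov=3,
        n_nk=50,
        n_dc=10,
        jitter_sd_um=0.5,
        planted_fraction=0.45,
        long_fraction_of_planted=0.01,
        condition="steady_state",
        fov_prefix="SS",
    ),
    "LPS": SimulationConfig(
        seed=12,
        n_fov=3,
        n_nk=50,
        n_dc=10,
        jitter_sd_um=0.5,
        planted_fraction=0.52,
        long_fraction_of_planted=0.12,
        condition="LPS",
        fov_prefix="LPS",
    ),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for name, config in CONDITIONS.items():
        fovs, gt = simulate_cohort(config)
        tracks_path = RESULTS / f"tracks_{name}.csv"
        write_tracks(fovs, tracks_path)
        pd.DataFrame([dataclasses.asdict(r) for r in gt]).to_csv(
            RESULTS / f"ground_truth_{name}.tsv", sep="\t", index=False
        )
        n_long = sum(1 for r in gt if r.intended_class == "long")
        print(
            f"{name}: {len(fovs)} FOVs, {sum(len(f.nk_tracks) for f in fovs)} NK "
            f"tracks, {len(gt)} planted contacts ({n_long} long) -> {tracks_path}"
        )


if __name__ == "__main__":
    main()
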