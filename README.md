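# nkcontacts

Detection and timing of dendritic-cell–natural-killer-cell (DC–NK)
interactions in 3D cell-tracking data from two-photon lymph-node imaging,
with the cohort statistics built on top and a synthetic track generator
for end-to-end validation.

## The problem

NK cells are activated in lymph nodes by contact with DCs, and the
*duration* of those contacts carries the biology: at steady state NK
cells mostly "touch and go", while under inflammation a subpopulation
holds stable synapses for 15 minutes or more. Calling an interaction by
eye, or by proximity alone, is unreliable — fast NK cells routinely pass
within contact range of a DC without engaging. This package implements a
user-independent detector that combines three per-frame criteria on
tracked cells. NK cell *i* is interacting with a DC at frame *t* iff,
simultaneously:

1. **proximity** — centroid distance `Dist(t) ≤ d`, with `d = 25 μm`;
2. **slowing** — instantaneous speed `v(t) ≤ α·V_FOV`, with `α = 0.60`
   and `V_FOV` the mean of per-track mean speeds of the NK cells in the
   field of view;
3. **confinement** — the confinement ratio
   `CR(t) = |r(t) − r(0)| / L(t)` (net displacement over trace length)
   is locally non-increasing: `CR(t) ≤ CR(t−1) + ε`, `ε = 0.01`.

An interaction *event* is a maximal run of consecutive frames satisfying
all three, refined by a tolerance rule: an isolated interior frame at
which exactly one criterion fails, flanked by fully qualifying frames, is
absorbed into the event. Two consecutive failures, or a tracking gap,
always split events. Duration is `n_frames × Δt`; events are classed
touch-and-go (< 5 s), long (≥ 900 s) or intermediate. A distance-only
baseline is provided for comparison and demonstrably over-calls contacts.

## Worked example

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_detect_interactions.py
python analysis/03_cohort_statistics.py
```

which prints (numbers from the fixed seeds in the scripts):

```
steady_state: 44.0% of 150 NK cells interacting (planted 44.0%), 1.5% of interacting cells in long contacts, mean contact 5.2 min
LPS: 52.0% of 150 NK cells interacting (planted 52.0%), 12.8% of interacting cells in long contacts, mean contact 6.8 min
interacting-cell 3D velocity, steady vs LPS: 8.57 vs 8.25 μm/min (t = 1.59, p = 0.115)
contact duration, steady vs LPS: 311 vs 408 s (t = -2.31, p = 2.19e-02)
```

Reading: the detector recovers exactly the planted interacting fractions
of the two synthetic cohorts (44% vs 52%), the long-contact fraction among
interacting cells rises from ~1% to ~13% under the inflammation-like
planting, mean contact duration shifts accordingly, while per-cell 3D
velocities of interacting cells stay statistically indistinguishable —
long-interacting cells are too few to move the cohort mean.
`analysis/04_recovery_benchmark.py` sweeps planted fractions
(10–90%) and verifies recovery within 95% binomial intervals.

The same pipeline is scriptable on any track table:

```bash
nkcontacts simulate --config sim.yaml --out sim/
nkcontacts detect --tracks sim/tracks.csv --out det/ --diagnostics
nkcontacts acceptance --out checks/
```

`detect` accepts any CSV with columns
`fov_id,condition,cell_id,cell_type,frame,time_s,x_um,y_um,z_um`
(μm, seconds; one row per cell per frame) and writes an events table,
per-track motility metrics and a per-condition cohort summary JSON.

## Library layout

- `nkcontacts.trackio` — track table I/O, data model, validation
- `nkcontacts.motility` — speeds, confinement ratio, FOV-average speed
- `nkcontacts.detection` — criteria, event segmentation, classification,
  distance-only baseline
- `nkcontacts.cohort` — interacting/long fractions, duration and velocity
  summaries, condition comparisons (two-tailed unpaired t-tests, mean ± SEM)
- `nkcontacts.simulate` — persistent-random-walk generator with planted
  contact episodes and ground truth
- `nkcontacts.validation` — boundary scans and recovery battery
- `nkcontacts.cli` — the `nkcontacts` command

See `docs/methods.md` for the model, parameter and design documentation.

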