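# Methods

## Data model

A *field of view* (FOV) is one imaged lymph-node volume: a set of
co-registered trajectories (NK, DC or T cells) on a shared frame clock.
Tracks are centroid positions in μm; time stamps in seconds. The frame
interval is never hard-coded: it is read per FOV and inferred from files
as the median inter-frame gap, which is robust to dropped frames and row
order. Tracking gaps are tolerated at read time, reported as
informational findings, and handled by the detector (a gap always
terminates an event run — an unobserved frame is absent data, not a
tolerable failure).

## Motility metrics

Instantaneous speed is the per-frame finite difference in μm/min; the
first frame copies the second so criterion series stay full-length. The
confinement ratio is cumulative from the track start,
`CR(t) = |r(t) − r(0)| / L(t)` with `CR(0) := 1` (an unmoved cell is
maximally straight); it lies in [0, 1] by the triangle inequality. The
phrase "distance run over trace length" admits either quantity in the
numerator; we adopt the standard convention that keeps CR in [0, 1] and
makes 1 ballistic and 0 fully confined.

The FOV-average speed `V_FOV` — the base of the relative speed
criterion — is the mean of per-track mean speeds (a two-stage mean, so
short and long tracks weigh equally). The averaging base is the NK
tracks by default: DCs are near-sessile and would drag an "all tracked
cells" average toward zero, making the 60% threshold meaninglessly easy
to satisfy. The cell-type set is configurable and recorded in output
metadata.

## Interaction detector

Per-frame criteria for an NK–DC pair, evaluated on the frames shared by
both tracks:

- distance: `Dist ≤ d` (inclusive), default `d = 25 μm`;
- speed: `v ≤ α·V_FOV` (inclusive), default `α = 0.60`;
- confinement: `CR(t) ≤ CR(t−1) + ε`, default `ε = 0.01`; false at the
  pair's first shared frame (no predecessor — a conservative start).

Both thresholds are inclusive; the boundary has measure zero in real
data but fixing it makes the contract testable. Speed and CR are
properties of the NK track alone and are computed on the full track
before restriction to shared frames.

Events are maximal runs of consecutive shared frames with all three
criteria true. The tolerance refinement absorbs an isolated interior
frame failing exactly one criterion when both neighbours fully qualify;
absorbed frames count toward the duration and are tallied separately.
This reading keeps events maximal while never bridging two consecutive
failures. Duration is `n_frames × Δt` — a one-frame contact lasts one
frame interval, not zero — so a planted k-frame contact recovers k·Δt
exactly. Classes: touch-and-go `< 5 s`, long `≥ 900 s`, intermediate
otherwise. The touch-and-go cut-off of 5 s is shorter than any plausible
two-photon frame interval and is kept configurable; the long boundary is
inclusive (≥ 15 min). An NK cell may hold simultaneous events with
different DCs; no tie-breaking suppresses them.

`detect_all` optionally skips pairs whose distance never drops below 2d;
since events require `Dist ≤ d`, gating cannot change results (asserted
by test).

## Cohort statistics

- interacting fraction: % of tracked NK cells with ≥ 1 event;
- long fraction: % of *interacting* cells whose **longest** event is
  long — a per-cell statement, so one long contact among many short ones
  counts the cell once. The companion readout normalised by all tracked
  cells is also emitted, since published summaries use both denominators;
- duration and per-cell 3D velocity distributions with mean ± SEM
  (SEM = sd/√n, sd with the n−1 denominator);
- condition comparisons: unpaired two-tailed Student t-test (equal
  variance); a zero pooled variance is flagged rather than raised. The
  paired variant is out of scope because the cohorts compared here are
  independent fields of view.

## Synthetic track generator

The generator emulates the imaging setting the detector assumes, not
lymph-node anatomy. Defaults: 30 s frames, 60-frame (30 min) movies,
300 × 300 × 60 μm volume with elastic walls, 10 ± 2 μm/min NK and T
cells (matching reported lymph-node lymphocyte speeds), DCs wobbling
≤ 5 μm around anchors ≥ 55 μm apart at 0.3 μm/min, heading persistence
0.6, localization jitter 0–0.5 μm, optional frame drops.

Design choices that matter:

- **Truncated speed distribution.** Per-step speeds are Normal(μ, σ)
  truncated symmetrically at ±1.5σ. The symmetric cut keeps the mean
  exactly μ (the speed-calibration test demands the estimated cohort
  speed within 2% of target) and floors roaming speeds at 0.7μ, safely
  above the 60% criterion — so a roaming cell can never qualify on speed
  and the planted episode table is a sharp ground truth.
- **Wall bounces flip the step, not the endpoint**, preserving step
  length so recorded displacements carry the drawn speed exactly;
  endpoint reflection would fold paths and bias measured speeds low.
- **Self-consistent dwell speed.** A planted episode's dwell speed is a
  fraction β (default 0.25) of the cohort-average speed, but the cohort
  average itself falls as cells dwell. The linear fixed point
  `v_dwell = β·μ(1−ḡ)/(1−ḡβ)` (ḡ = dwell steps over all NK steps) is
  solved exactly, so episodes stay below the speed threshold for any
  planted load — including a single pair dwelling for most of the movie,
  the regime of the duration-boundary scans.
- **Dwell geometry.** During a dwell the cell makes small steps that
  never increase its net displacement from the track origin (outward
  radial components are removed; far from the origin a small inward bias
  is added), stays within the dwell radius (default 10 μm) of the DC,
  and falls back to a zero step when no compliant move exists. This
  guarantees a non-increasing confinement ratio throughout the episode,
  noiselessly exact and robust to 0.5 μm jitter up to occasional
  isolated failures that the detector's tolerance absorbs.
- **Approach and departure.** The cell arrives beside its DC one frame
  before the dwell via full-speed closure and loitering, and leaves at
  full speed for three frames afterwards; since all non-dwell steps move
  at roaming speed, the detected event starts and ends exactly on the
  planted frames.
- **Keep-out radius for non-planted cells** (default 30 μm = d + jitter
  margin). Under localization noise a roaming cell passing within d of a
  DC can transiently satisfy the full operational definition (an
  apparent slow frame with drifting-down CR). Those frames *are*
  interactions by the operational definition, so a recovery benchmark
  against a planted table is only well-posed if non-planted cells stay
  out of contact range; the keep-out enforces that. Null-specificity
  experiments use the stricter 2d separation.

What the generator does **not** emulate: T-cell-zone geometry and
chemokine fields, cell shape and surface contact (centroids only),
tracking identity switches, anisotropic (z-dominant) localization error,
and drift of the imaging stage. Passing recovery tests therefore shows
the detector recovers contacts of the kind it defines under realistic
noise and sampling — not that biological contacts obey the three
criteria.

## Numerical choices and degenerate inputs

- CR is clipped to [0, 1] against floating overshoot of the triangle
  bound; `0/0` at the first frame resolves to 1.
- Criterion comparisons are plain inclusive floating comparisons; scans
  use values exactly representable or constructed symmetrically, so no
  epsilon fudging is needed.
- Single-point tracks, empty pair overlaps, zero-variance samples and
  empty event sets return typed findings/flags rather than exceptions
  wherever the result is representable.
- Determinism: every stochastic component takes an explicit seed; FOV
  streams derive from (seed, fov index) so fields of view are
  independently reproducible; CLI data outputs are byte-identical under
  rerun (the run manifest alone carries a timestamp).

## Problem sizes

Validation suites use 100 NK cells and 10 DCs per FOV over 60 frames
with 20 replicates per condition for recovery (95% binomial intervals on
pooled counts), 50 replicates for null specificity, 1000+ random
sequences for the segmentation oracle, and 200-track cohorts for speed
calibration — sizes chosen to make binomial intervals informative at the
fractions of interest while keeping the full battery interactive.

## Known limitations

- The confinement criterion is local (frame-to-frame); a slow upward
  drift of CR within an event is tolerated as long as each step stays
  within ε. This matches the qualitative "constant or decreasing"
  definition but differs from a global monotonicity constraint.
- The tolerance rule is defined for observed frames only; datasets with
  heavy frame-dropping will fragment long events rather than bridge
  them.
- `V_FOV` mixes interacting and free cells by design (it is defined over
  all tracked NK cells); in fields where most cells dwell, the speed
  threshold adapts downward, which is intended but worth knowing when
  comparing across very different planted loads.
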