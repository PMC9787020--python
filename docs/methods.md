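# Methods

`herdlab` simulates a collaborative search-and-corral task — three players
herd autonomous target agents (TAs) into a small containment disc on a
large plane — and measures the resulting behavior with the same pipeline
used for human teams in that task: trial duration with right censoring at
the trial cap, search-area overlap from alpha shapes, detrended
fluctuation analysis (DFA) of 5 Hz movement-angle series, and
log-logistic accelerated failure time (AFT) regression of completion
times. This note records the model, the parameter choices that matter,
and what the synthetic generator does and does not emulate.

## Task model

The arena is a 500 × 500 m square with a 10 m diameter containment disc
at its center. A trial runs at 90 Hz for at most 300 s and succeeds when
every TA has remained inside the disc for 5 continuous seconds; a single
frame outside resets the hold timer. Failed trials record their duration
at the 300 s ceiling.

Each TA is a 1 kg point mass integrated with semi-implicit Euler at
1/90 s. Three forces act on it:

* **Brownian forcing** — a force with magnitude uniform on [0, 60] N and
  uniform planar direction, redrawn once per simulated second and held
  constant in between (a 1 Hz piecewise-constant process).
* **Avatar repulsion** — when a player avatar is within 10 m, a force
  directed from the avatar toward the TA with magnitude
  `min(450, 450 / d)` N at distance `d` m. The inverse-distance law with
  `c = 450 N·m` is the single-parameter choice consistent with an
  inverse-proportional falloff and a 450 N cap (the cap engages at
  d ≤ 1 m). At exactly zero distance the direction is degenerate and the
  cap magnitude is returned along +x. Repulsions from multiple avatars
  add.
* **Linear drag** — `−γ·v` with γ = 10 s⁻¹ by default (configurable).
  The underlying game engine applies drag implicitly and no value is
  documented, so γ is this package's calibration. The value is chosen on
  physical grounds: the terminal speed of a Brownian kick of magnitude F
  is `min(F/γ, 10)` m/s, so at γ = 1 the TAs sit at the 10 m/s speed cap
  roughly 5/6 of the time, cross the containment disc in about a second
  indefinitely, and the 5 s all-contained hold becomes unattainable for
  any play — every trial would censor, contradicting the observed mix of
  successes and failures in this task. At γ = 10 unperturbed TAs roam
  diffusively at ~3 m/s (mean step ≈ 3 m per kick), while fleeing TAs
  near an avatar still reach the 10 m/s cap. Velocity is capped by
  rescaling after integration.

TA speeds are capped at 10 m/s. Positions are clamped to the arena with
the outward velocity component zeroed. Avatars move kinematically at
exactly 10 m/s (5 m/s in slow mode) with no collision physics, matching
the stated speeds without inventing avatar dynamics.

Spawning is area-uniform on discs centered on the containment point
(`r = R·√u`): players within 100 m, TAs within 180 m, with no exclusion
zone. TA status is idle / fleeing (an avatar within 10 m) / contained
(inside the closed disc, which takes precedence over fleeing) /
all-contained.

All randomness descends from one root seed through named substreams
(spawn, Brownian, one per policy), so a trial is bit-reproducible and
policies can be swapped without perturbing the world's draws.

## Scripted policies

Scripted players stand in for human teams. They are explicitly
synthetic: they emulate the *conditions* (what players can see and know),
not any particular human strategy, and no behavioral equivalence to
human teams is claimed.

Sensing: with `global_info` (HUD emulation) the observation carries every
avatar and TA with statuses and velocities; otherwise only entities
within `sense_radius` (≈10 m emulates fog, ≥150 m clear skies). The
containment disc location is always available, as both the HUD and the
compass display it as a landmark.

Acting, in priority order:

1. **Corral** — pick a threat (a visible uncontained TA, or a contained
   TA drifting past 50% of the disc radius). When teammates are visible,
   threats are notionally assigned to the nearest visible player so
   players split targets without communicating. The player orbits the
   target outside its repulsion zone until within the 60° cone behind it
   (relative to the disc), then drives at a stand-off point on the
   outward ray so the repulsion pushes the target inward. The stand-off
   is 2.5 m during long-range herding (strong push, near-cap flight) but
   8 m near the disc, where the weaker inverse-distance force nudges the
   target in instead of launching it across. The push aims at the
   target's velocity-led position.
2. **Guard** — when every known TA is safely contained (or under the
   `corral_nearest` strategy with nothing to chase), stand just outside
   the disc at the azimuth of the i-th outermost contained TA, where
   escapes are most likely to start.
3. **Search** — otherwise follow the strategy's waypoint generator:
   `partitioned_sweep` walks a golden-angle spiral folded into the
   player's own 120° wedge; `shared_sweep` walks the full spiral (all
   players the same route); `random_walk` draws uniform headings.

Head orientation is the movement heading plus a sinusoidal scan
(amplitude 0.6 rad, period 2 s, per-player phase) plus Gaussian noise
(SD 0.05 rad) — a synthetic stand-in for mouse-driven visual scanning
that gives the head-orientation channel nondegenerate fluctuation
structure. Decisions are recomputed at 15 Hz and held between decisions,
mimicking coarser-than-frame-rate steering.

## Fluctuation series and DFA

Player tracks are decimated from the 90 Hz log to 5 Hz (every 18th
sample, no filtering — the minimal reading of "downsampled") and the
first second of retained samples is deleted to remove transients. Two
series are built per player: the displacement angle
`atan2(Δy, Δx)` between adjacent 5 Hz positions (raw angles, no
unwrapping; a stationary frame holds the last defined angle, 0 before
any motion — both choices are toggleable), and the wrap-aware change in
head orientation, mapped to (−π, π]. A full failed trial yields
1495 retained positions and hence 1494-sample series.

DFA subtracts the series mean, integrates, and detrends windows placed
with 50% overlap, with sizes starting at 5 samples (1 s) and growing by
the factor 1.2 (rounded to integers, deduplicated) while strictly below
10% of the series length. Within each window a least-squares polynomial
(degree 1 by default) is removed and the residual SD taken; the
per-window SDs are averaged arithmetically by default, with the more
common root-mean-square convention available behind a switch (the two
agree closely for the stationary series handled here). The slope of log₁₀ fluctuation on log₁₀ window size is
the scaling exponent α. Series shorter than 50 samples are rejected
(no admissible second window). Calibration: over 50 seeded series of
length 1495, mean α is ≈0.5 for white noise, ≈1.0 for spectrally
synthesized 1/f noise, ≈1.5 for integrated white noise, and ≈0.08 for
differenced white noise.

## Search-area overlap

A player's search polygon is the tightest single bounding polygon of its
5 Hz positions. From the Delaunay triangulation, triangles with
circumradius above `1/α` are discarded; the shape parameter is bisected
on [0, α_max] (α_max = 4 / median nearest-neighbor spacing, tolerance
1e-4·α_max, 1000-iteration cap) for the largest α whose kept triangles
form one edge-connected component covering every input point. The
geometry is then built once at that α; if the search fails or the result
is not a single valid polygon, the convex hull is used. Holes are
permitted and excluded from the area. Degenerate inputs (<3 points,
collinear) yield zero area with an explicit flag.

The overlap proportion is the area covered by at least two players'
polygons (union of pairwise intersections; triple-covered patches count
once) divided by the union area of all polygons — 0 for a cleanly
partitioned search, 1 for identical search areas. Boolean operations and
areas are exact polygon arithmetic (GEOS).

## Survival modeling

Trial duration is modeled as log-logistic AFT:
`log T = x'β + σW` with standard-logistic `W`, so
`S(t|x) = 1 / (1 + (t/e^{x'β})^{1/σ})` and the conditional median is
`e^{x'β}` exactly. Successes are events; failures are right-censored at
the 300 s ceiling (a failure says only that completion would have taken
longer than the cap). Estimation is maximum likelihood over
`(β, log σ)` by BFGS with an analytic gradient, started from the
log-median of event times and an IQR-based σ (logistic IQR = 2σ·log 3)
plus dispersed restarts; convergence requires a gradient ∞-norm below
1e-6. Standard errors come from the inverse numerical Hessian; when a
team/cluster column is supplied, cluster-robust sandwich errors replace
the original random team effect, which is out of scope. Nested fits
report the LR statistic and AIC, satisfying ΔAIC = 2·Δparams − LR. A fit
with zero events is refused as non-identifiable (the likelihood
increases without bound in the intercept).

## Experiment orchestration

The emulated 2×2×2 design crosses visibility (fog: 10 m sense radius;
clear: 150 m), information (HUD: global; compass: local), and target
count (9 / 18); strategy is an orthogonal factor rather than a
condition, so policy effects can be studied separately. Per-trial seeds
derive deterministically from the root seed and (cell, replicate)
indices and are recorded in each trial's manifest. Per-cell summaries
use means with 2,000-resample percentile-bootstrap intervals rather than
mixed models, which are out of scope.

## What the generator reproduces, and what it does not

With the scripted policies, the simulator reproduces the qualitative
structure of the human results: information-rich cells (clear, HUD)
complete faster than information-poor ones; 18-target trials take longer
than 9-target trials; partitioned search produces far lower overlap
proportions (≈0.0–0.2) than shared-route search (≈0.8); and teams whose
players show higher head-orientation DFA α complete faster — both the
trial-level Spearman association and the sign of the AFT coefficient
match the human result.

Two aspects of the human data are *not* reproduced, and tests do not
claim them. First, the **displacement-angle** DFA α of scripted players
is highest in slow, fog-bound sweep trials (a spiral sweep is an
extremely persistent heading process, α ≈ 1.9) and lower in fast
corralling trials (α ≈ 1.0), so across conditions its association with
duration is positive rather than negative; direction checks involving
persistence therefore use the head-orientation channel. Second, the
overlap proportion carries no duration signal beyond the condition
means: scripted sectors stay equally disjoint regardless of visibility
(humans overlapped *more* under fog, the scripts slightly less), and
duration variance within a cell is dominated by endgame containment
luck, so the trial-level overlap-duration correlation is ≈0. The
`direction_checks` helper still computes that flag for data where the
association exists. Both divergences are properties of
waypoint-following scripts, not of the measurement pipeline: passing
tests show the pipeline measures what it claims on data with known
structure, not that scripted policies move like people.

Other simplifications: no avatar collision physics, no communication,
no learning across sessions, no trial blocks or lobby logic, and
synchronized 1 Hz Brownian redraws across TAs.

## Problem sizes used in the test suite

Calibration uses 50 series of length 1495 (the length a full failed
trial yields). The simulator contract is checked on seeded full-length
trials plus 1,000 spawn initializations. Oracle equivalence uses 20
fixed-seed series (DFA) and 10 polygon fixtures against a 4×10⁵-sample
Monte-Carlo area oracle. AFT recovery uses 100 replicates of n = 500
with ~25% censoring. The direction suite runs 20 seeds in each of four
design cells (80 full trials); these sizes keep the whole suite
comfortably reproducible on a single CPU.
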