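# Methods

## The model

Sperm cells in a growing pollen tube are enclosed in a spindle-shaped
microtubule cage. KCH kinesins (kinesin-14 family, minus-end directed,
actin-anchored via their calponin homology domain) link the cage to cortical
actin cables; depending on the polarity of the microtubule a motor engages,
it pushes the cage toward the tube apex ("forward", +x) or back toward the
pollen grain ("backward", −x). `kchtow` models this as a two-team tug-of-war
in the mean-field rigid-coupling tradition of Müller-type motor models.

A single pool of `N` motors feeds two teams. A bound motor of team *i* has

- a linear force–velocity relation `v_i(F) = v_F,i (1 − F/F_s,i)` for loads
  `F ≤ F_s,i`, continuing above stall as the shallow backslip branch
  `v_B,i (1 − F/F_s,i)` (negative, slow);
- a constant binding rate `π_0,i` (per unbound motor in the pool);
- a load-dependent unbinding rate `ε_i(F) = ε_0,i exp(|F|/F_d,i)`.

With `n₊` and `n₋` motors bound, each team shares the cargo tension
equally (`F_c/n₊` and `F_c/n₋` per motor). Matching the two teams'
velocities, the dominant team (larger total stall load `n·F_s`) sets

```
F_c = λ n₊F_s₊ + (1−λ) n₋F_s₋,      λ = 1 / (1 + n₊F_s₊ v_B₋ / (n₋F_s₋ v_F₊))
v_c = (n₊F_s₊ − n₋F_s₋) / (n₊F_s₊/v_F₊ + n₋F_s₋/v_B₋)
```

for forward dominance, mirrored (`v_F₊→v_B₊`, `v_B₋→v_F₋`) for backward
dominance. These closed forms are the unique pair satisfying the defining
consistency relation `v_c = v₊(F_c/n₊) = −v₋(F_c/n₋)`, which the test suite
verifies to 1e-9 relative tolerance over random parameter sets. Degenerate
cases bypass the λ machinery: no bound motor → the cargo rests (`F_c = v_c
= 0`); one team only → unloaded motion at that team's `v_F`; equal stall
loads → both teams stall (`v_c = 0`, `F_c = n₊F_s₊`).

The bound-motor state `(n₊, n₋)` is a continuous-time Markov chain with
four channels: binding to either team at `(N − n₊ − n₋)·π_0,i` and
unbinding at `n_i · ε_i(F_c/n_i)`. It is simulated exactly with the
Gillespie algorithm (exponential waiting time at the total rate, channel
chosen proportionally); the cargo advances at the piecewise-constant `v_c`
of the pre-event state. Trajectories are clipped exactly at the requested
duration and downsampled to a uniform frame interval by linear
interpolation between event epochs, emulating the frame rate of
experimental particle tracking.

## Default parameters

| parameter | forward team | backward team | unit |
|---|---|---|---|
| stall force `F_s` | 3 | 3 | pN |
| detachment force `F_d` | 10 | 10 | pN |
| binding rate `π_0` | 0.7 | 0.6 | s⁻¹ |
| unbinding rate `ε_0` | 1.7 | 1.6 | s⁻¹ |
| forward speed `v_F` | 0.08 | 0.01 | μm s⁻¹ |
| backslip speed `v_B` | 0.008 | 0.001 | μm s⁻¹ |

Total motors `N = 70`. Internal units are pN, μm, s; the analysis layer
reports velocities in nm/s, the scale of the data. Each parameter block is
read as the constants of one motor team (the `v_B` listed with a team is
that team's own superstall backslip). The simulation defaults are 21 tracks
of 3600 s per cohort: track duration is not prescribed by the source data,
and one hour yields enough runs per track (tens to hundreds) for stable
per-track means while keeping a full cohort under ~15 s of compute.

Simulation starts from the fully unbound state `(0, 0)`; binding/unbinding
rates of order 1 s⁻¹ equilibrate the state within seconds, negligible over
hour-long tracks. An optional burn-in (default 0 s) is available.

## Trajectory evaluation

The analysis consumes any uniformly sampled 1-D track (simulated,
synthetic, or experimental CSV) through one code path:

1. **Point-to-point displacements.** Signed displacement and velocity per
   consecutive frame pair.
2. **Run/pause segmentation.** Intervals with `|v| ≤ 1 nm/s` are pauses
   (ties deterministically classed as pauses); maximal blocks of
   consecutive same-class intervals merge into runs. The merging rule is
   read permissively — a single qualifying interval is a run — with
   `min_intervals_per_run=2` implementing the stricter reading (shorter
   directional blocks are reclassified as pauses, so no time is dropped).
   Run length is reported as duration in seconds; path displacement in μm
   is carried alongside.
3. **Displacement-weighted velocity distributions.** Per direction, each
   interval contributes weight `|Δx|` to a histogram (default bin width
   1 nm/s) of interval velocities; a Gaussian `a·exp(−(v−μ)²/2σ²)` is
   least-squares fitted to bin centers vs weights, initialized from the
   displacement-weighted moments, with μ constrained to the histogram
   support and σ to its width (unbounded fits diverge on broad multimodal
   histograms). Fits require ≥ 4 populated bins; otherwise the weighted
   moments stand in, flagged via `fit_ok`.
4. **Cohort comparison.** Per-track fitted forward mean vs backward
   magnitude, and mean forward vs backward run duration, compared with a
   paired two-sided t-test (n tracks as pairs); a Wilcoxon signed-rank
   alternative is available. The source analysis names no test; both are
   standard for a paired n=21 design.

Backward velocities are stored signed (negative) and compared as
magnitudes.

## Synthetic ground-truth tracks

Raw in vivo tracks are unpublished, so the analysis stage is validated
against a generator of piecewise-constant-velocity tracks (forward runs,
backward runs, pauses) sampled at a uniform frame interval with i.i.d.
Gaussian localization noise per frame. Defaults follow the published in
vivo regime: forward runs 10.85 ± 1.93 nm/s and 44.89 ± 39.69 s, backward
runs 9.06 ± 4.45 nm/s and 32.03 ± 25.15 s. Pause durations (unpublished)
default to 25 ± 20 s, between the two run-duration means, as kymographs
show pauses comparable to runs. Durations and speeds are drawn from
truncated normals (the published statistics give mean ± SD only; an
exponential family is available for durations), truncated at one frame
interval and at the pause threshold. Localization noise defaults to 10 nm,
a typical sub-pixel precision for FIESTA-class trackers; noise 0 is used
for exact-closure tests.

What the generator does *not* emulate: spatially correlated tracking
errors, drift, frame drops, gradual velocity changes within a run, or any
tug-of-war mechanics (that is the simulator's job). Passing closure tests
therefore shows the analysis is correct on idealized saltatory motion, not
that it is robust to every artifact of real microscopy. A known and
intended sensitivity: with threshold 1 nm/s at Δt = 5 s, localization
noise above a few nm makes pause intervals masquerade as slow runs
(interval velocity noise SD = √2·σ/Δt), fragmenting pauses; the recovered
pause fraction degrades monotonically with σ/(threshold·Δt).

## Numerical choices

- Per-state caching of channel rates and cargo velocity inside the SSA
  loop (the reachable state space is ≤ (N+1)(N+2)/2 while event counts
  reach millions), and block-buffered uniform draws; one 3600 s track at
  N=70 (~4·10⁵ events) takes well under a second.
- Per-track RNG streams are spawned from `(cohort_seed, track_index)`;
  identical seeds give bit-identical trajectories and reports.
- Downsampling never extrapolates beyond the final epoch; a frame
  interval longer than the trajectory span is an error.
- Velocity-threshold ties classify as pause; segmentation tiles the track
  with no gaps or overlaps, so run durations and displacements sum exactly
  to the track totals (asserted in tests).

## Reproduction scope and known limitations

`reproduce` regenerates the simulated cohort (21 tracks × 3600 s, N = 70,
Δt = 5 s) and reports cohort statistics next to the published simulated
values (forward 10.83 ± 0.76 nm/s, backward 6.77 ± 0.38 nm/s, run
durations 30.76 ± 1.66 s and 25.91 ± 1.40 s, both comparisons p < 0.05),
plus a frame-interval sensitivity table (Δt ∈ {2, 5, 10} s; the
experimental frame rate behind the published downsampling was never
reported) and a motor-number sweep (N ∈ {30, 50, 70, 100}, 7 tracks each —
a qualitative robustness check, so a smaller cohort suffices).

A substantive limitation, documented rather than hidden: under this
implementation of the stated equations and parameters, the chain relaxes
to a mixed state (⟨n₊⟩ ≈ 14, ⟨n₋⟩ ≈ 11) whose cargo velocity is mostly
sub-threshold, and net transport is carried by brief (~0.2 s) evacuation
bursts of the backward team at up to 80 nm/s. After 5 s downsampling this
yields strongly significant forward-dominated transport (the directional
asymmetry and its significance reproduce robustly, as does insensitivity
to N), but the cohort means differ from the published values: forward
velocities come out faster (~25 nm/s), backward magnitudes smaller
(~1.5 nm/s), and runs shorter (~9 s / ~6 s) at Δt = 5 s. Exact stationary
analysis of the motor-state chain shows why: with `F_d > F_s` the
load-detachment feedback is too weak to sustain the partial-dominance
states (e.g. n₊ ≤ 2 against n₋ ≈ 11 for ~26 s) that the published backward
run statistics imply, for any frame interval, merging rule, or pool
reading we examined. The sensitivity table quantifies how far frame-rate
choice alone can move these numbers.
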