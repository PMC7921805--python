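# kchtow — tug-of-war transport of sperm cells in pollen tubes

`kchtow` is a stochastic simulator and trajectory-analysis toolkit for the
saltatory movement of sperm cells inside growing pollen tubes. The sperm
cells ride in a spindle-shaped microtubule cage; KCH kinesins (kinesin-14
family, minus-end directed, anchored to cortical actin via their calponin
homology domain) engage microtubules of either polarity and so pull the
cage either toward the tube apex or back toward the pollen grain. The
package is aimed at researchers who want to regenerate the simulated
cohort behind that model, sweep its parameters, or push their own
particle-tracking trajectories through the identical evaluation pipeline.

## The model and the statistics

Two motor teams drawn from one shared pool of `N` motors pull the cargo in
opposite directions. A single motor of team *i* binds at a constant rate
`π₀,ᵢ`, unbinds at `εᵢ(F) = ε₀,ᵢ exp(|F|/F_d,ᵢ)`, and moves with the linear
force–velocity relation `vᵢ(F) = v_F,ᵢ (1 − F/F_s,ᵢ)` below stall,
continuing as a slow backslip `v_B,ᵢ (1 − F/F_s,ᵢ)` above stall. With
`(n₊, n₋)` motors bound, the teams share one cargo tension `F_c` and one
velocity `v_c` fixed by `v_c = v₊(F_c/n₊) = −v₋(F_c/n₋)`:

    v_c = (n₊F_s₊ − n₋F_s₋) / (n₊F_s₊/v_F₊ + n₋F_s₋/v_B₋)   (forward dominance)

The bound-motor counts evolve as a four-channel Markov jump process
simulated exactly with the Gillespie algorithm; event trajectories are
downsampled by linear interpolation to a uniform frame interval.

The analysis stage mirrors the evaluation applied to in vivo tracking
data: point-to-point displacements, a 1 nm/s pause threshold, merging of
consecutive same-direction intervals into runs, displacement-weighted
velocity histograms per direction with Gaussian fits (fitted mean ± SD are
the run velocities), mean run durations, and a paired forward-vs-backward
cohort test. See `docs/methods.md` for the full model account and design
choices.

## Worked example

Regenerate the 21-track simulated cohort (3600 s per track, N=70 motors,
5 s frames) and compare with the published simulated-cohort statistics:

```
$ kchtow reproduce --seed 1 --no-sweep --out rep
simulated cohort, n=21 tracks (3600.0 s, dt=5.0 s, N=70)
quantity                             this run        published
forward velocity [nm/s]         25.62 ±  3.35    10.83 ±  0.76
backward velocity [nm/s]         1.48 ±  0.06     6.77 ±  0.38
forward run duration [s]         9.05 ±  0.41    30.76 ±  1.66
backward run duration [s]        5.69 ±  0.21    25.91 ±  1.40
paired t (21 tracks): p_velocity=5.61e-19, p_run_duration=4.24e-19
net velocity 5.40 ± 0.52 nm/s
```

Reading the output: each row is the cohort mean ± SD over the 21 tracks of
a per-track statistic — the Gaussian-fit mean of the displacement-weighted
velocity distribution per direction, and the mean run duration per
direction. The qualitative signature reproduces robustly: net transport is
apexward, forward runs are significantly faster and longer than backward
runs (both p ≈ 10⁻¹⁹, published as p < 0.05), and this holds across motor
numbers 30–100. The cohort means themselves deviate from the published
values — faster forward, weaker backward, shorter runs — for reasons
analyzed in `docs/methods.md` (with `F_d > F_s` the load feedback cannot
sustain the long partially dominated excursions the published backward
statistics imply; the unknown experimental frame rate moves these numbers
substantially, which the report's `dt_sensitivity` table quantifies).

Other entry points:

```
kchtow simulate --n-tracks 21 --duration 3600 --dt 5 --seed 0 --out sim/
kchtow synth --seed 0 --out synth/          # ground-truth synthetic cohort
kchtow analyze --tracks sim/tracks.csv --threshold 1.0 --out results/
```

Track files are tidy CSV (`track_id, time_s, position_um`); `analyze`
writes the run segmentation, per-track statistics and cohort summary. The
same commands accept experimental tracker output in the same format.

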