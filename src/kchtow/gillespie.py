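"""Exact stochastic simulation of the motor-binding dynamics.

The bound-motor state ``(n_plus, n_minus)`` is a continuous-time Markov
chain with four event channels — binding to either team from the shared
unbound pool (rate ``(N - n_plus - n_minus) * pi_0`` per team) and
load-dependent unbinding from either team (rate
``n * epsilon_0 * exp((F_c/n)/F_d)``).  Waiting times are exponential at the
total rate and the cargo advances at the piecewise-constant velocity of the
pre-event state, producing event-stamped trajectories that are then
downsampled by linear interpolation to the uniform frame interval of
experimental tracking data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

from .motor_model import (
    MotorState,
    TugOfWarParams,
    cargo_mechanics,
    unbinding_rate,
)

__all__ = [
    "EventRates",
    "Trajectory",
    "SampledTrack",
    "event_rates",
    "step",
    "simulate",
    "simulate_cohort",
    "downsample",
    "track_seed",
]


@dataclass(frozen=True)
class EventRates:
    """The four SSA channel rates (per second) at one motor state."""

    bind_plus: float
    bind_minus: float
    unbind_plus: float
    unbind_minus: float

    @property
    def total(self) -> float:
        return self.bind_plus + self.bind_minus + self.unbind_plus + self.unbind_minus

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.bind_plus, self.bind_minus, self.unbind_plus, self.unbind_minus)


def event_rates(state: MotorState, params: TugOfWarParams) -> EventRates:
    """Channel rates at ``state``.

    Binding draws on the one shared pool of ``N - n_plus - n_minus`` unbound
    motors for both teams; unbinding is per bound motor at its share
    ``F_c / n`` of the cargo load.
    """
    n_plus, n_minus = state
    free = params.n_motors - n_plus - n_minus
    if n_plus < 0 or n_minus < 0 or free < 0:
        raise ValueError(f"invalid motor state {state!r} for N={params.n_motors}")
    mech = cargo_mechanics(MotorState(n_plus, n_minus), params)
    unbind_plus = 0.0
    if n_plus:
        unbind_plus = n_plus * unbinding_rate(mech.force_pN / n_plus, params.forward)
    unbind_minus = 0.0
    if n_minus:
        unbind_minus = n_minus * unbinding_rate(mech.force_pN / n_minus, params.backward)
    return EventRates(
        bind_plus=free * params.forward.binding_rate_per_s,
        bind_minus=free * params.backward.binding_rate_per_s,
        unbind_plus=unbind_plus,
        unbind_minus=unbind_minus,
    )


# channel index -> (dn_plus, dn_minus)
_CHANNEL_DELTAS = ((1, 0), (0, 1), (-1, 0), (0, -1))


def step(
    state: MotorState, params: TugOfWarParams, rng: np.random.Generator
) -> tuple[float, MotorState]:
    """One SSA step: exponential waiting time at the total rate, channel
    chosen proportionally to its rate.  Returns ``(tau, new_state)``."""
    rates = event_rates(state, params)
    r_tot = rates.total
    if r_tot <= 0.0:
        raise RuntimeError(f"total rate vanished at state {state!r}: corrupt state")
    tau = rng.exponential(1.0 / r_tot)
    u = rng.random() * r_tot
    acc = 0.0
    for channel, rate in enumerate(rates.as_tuple()):
        acc += rate
        if u < acc:
            break
    dp, dm = _CHANNEL_DELTAS[channel]
    return tau, MotorState(state.n_plus + dp, state.n_minus + dm)


@dataclass
class Trajectory:
    """Event-stamped cargo trajectory from one SSA run.

    ``times_s`` are the (non-uniform) event epochs starting at 0,
    ``positions_um`` the cargo positions (+ = apexward, 0 at start), and
    ``n_plus``/``n_minus`` the bound-motor counts holding *from* each epoch
    until the next one.
    """

    times_s: np.ndarray
    positions_um: np.ndarray
    n_plus: np.ndarray
    n_minus: np.ndarray
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        n = len(self.times_s)
        if not (len(self.positions_um) == len(self.n_plus) == len(self.n_minus) == n):
            raise ValueError("trajectory arrays must have equal length")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    @property
    def n_events(self) -> int:
        return len(self.times_s) - 1


@dataclass
class SampledTrack:
    """Uniformly sampled 1-D position series, the common currency of the
    analysis stage.  ``provenance`` is one of ``"simulated"``,
    ``"synthetic"``, ``"experimental"`` and only annotates."""

    track_id: str
    frame_interval_s: float
    times_s: np.ndarray
    positions_um: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.positions_um):
            raise ValueError("times and positions must have equal length")
        if not np.all(np.isfinite(self.positions_um)):
            raise ValueError("positions must be finite")

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    @property
    def n_frames(self) -> int:
        return len(self.times_s)


def _validate_params(params: TugOfWarParams) -> None:
    for key, value in params.to_dict().items():
        if not math.isfinite(value):
            raise ValueError(f"non-finite parameter {key}={value!r}")


def simulate(
    params: TugOfWarParams,
    duration_s: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    burn_in_s: float = 0.0,
) -> Trajectory:
    """Run the SSA from the fully unbound state for ``duration_s`` seconds.

    Between events the cargo advances at the velocity of the pre-event
    state; the final epoch is interpolated exactly at ``duration_s`` so the
    trajectory spans ``[0, duration_s]``.  An optional ``burn_in_s`` is
    simulated first and discarded (position and clock reset), leaving the
    motor state equilibrated.  Identical ``seed`` gives a bit-identical
    trajectory.
    """
    _validate_params(params)
    if not math.isfinite(duration_s) or duration_s < 0:
        raise ValueError(f"duration_s must be >= 0, got {duration_s!r}")
    if burn_in_s < 0:
        raise ValueError("burn_in_s must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    # Per-state cache: the reachable state space is small (<= (N+1)(N+2)/2)
    # while event counts run into the millions, so rates and velocities are
    # computed once per state.
    cache: dict[tuple[int, int], tuple[float, float, float, float, float]] = {}

    def lookup(key: tuple[int, int]):
        entry = cache.get(key)
        if entry is None:
            rates = event_rates(MotorState(*key), params)
            c1 = rates.bind_plus
            c2 = c1 + rates.bind_minus
            c3 = c2 + rates.unbind_plus
            r_tot = c3 + rates.unbind_minus
            v = cargo_mechanics(MotorState(*key), params).velocity_um_s
            entry = (c1, c2, c3, r_tot, v)
            cache[key] = entry
        return entry

    # Uniform draws are consumed in blocks; scalar Generator calls dominate
    # the runtime otherwise.
    _BLOCK = 8192
    buf = rng.random(_BLOCK)
    idx = 0

    def uniform() -> float:
        nonlocal buf, idx
        if idx == _BLOCK:
            buf = rng.random(_BLOCK)
            idx = 0
        u = buf[idx]
        idx += 1
        return u

    def advance(n_p: int, n_m: int, t: float, x: float, horizon: float, record: bool):
        times = [t] if record else None
        positions = [x] if record else None
        nps = [n_p] if record else None
        nms = [n_m] if record else None
        while t < horizon:
            c1, c2, c3, r_tot, v = lookup((n_p, n_m))
            tau = -math.log(1.0 - uniform()) / r_tot
            if t + tau >= horizon:
                x += v * (horizon - t)
                t = horizon
                if record:
                    times.append(t)
                    positions.append(x)
                    nps.append(n_p)
                    nms.append(n_m)
                break
            t += tau
            x += v * tau
            u = uniform() * r_tot
            if u < c1:
                n_p += 1
            elif u < c2:
                n_m += 1
            elif u < c3:
                n_p -= 1
            else:
                n_m -= 1
            if record:
                times.append(t)
                positions.append(x)
                nps.append(n_p)
                nms.append(n_m)
        return n_p, n_m, times, positions, nps, nms

    n_p, n_m = 0, 0
    if burn_in_s > 0:
        n_p, n_m, *_ = advance(n_p, n_m, 0.0, 0.0, burn_in_s, record=False)
    _, _, times, positions, nps, nms = advance(n_p, n_m, 0.0, 0.0, duration_s, record=True)
    return Trajectory(
        times_s=np.asarray(times, dtype=float),
        positions_um=np.asarray(positions, dtype=float),
        n_plus=np.asarray(nps, dtype=np.int32),
        n_minus=np.asarray(nms, dtype=np.int32),
        seed=seed,
    )


def track_seed(cohort_seed: int, track_index: int) -> np.random.SeedSequence:
    """Per-track seed derived from the cohort seed and the track index."""
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(track_index,))


def simulate_cohort(
    params: TugOfWarParams,
    n_tracks: int,
    duration_s: float,
    seed: int,
    burn_in_s: float = 0.0,
) -> Iterator[Trajectory]:
    """Yield ``n_tracks`` independent trajectories; track ``i`` uses the RNG
    stream spawned from ``(seed, i)`` so single tracks and whole cohorts are
    individually reproducible."""
    for i in range(n_tracks):
        rng = np.random.default_rng(track_seed(seed, i))
        traj = simulate(params, duration_s, rng=rng, burn_in_s=burn_in_s)
        traj.seed = seed
        yield traj


def downsample(
    traj: Trajectory,
    frame_interval_s: float,
    track_id: str = "sim",
    provenance: str = "simulated",
) -> SampledTrack:
    """Resample an event trajectory on the uniform grid ``k * dt`` by linear
    interpolation between the bracketing event epochs.  The grid never
    extends beyond the final epoch (no extrapolation)."""
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    span = traj.times_s[-1] - traj.times_s[0]
    if span < frame_interval_s:
        raise ValueError(
            f"trajectory span {span} s is shorter than frame interval {frame_interval_s} s"
        )
    # tiny relative slack so a span that is an exact multiple keeps its endpoint
    n_frames = int(math.floor(span / frame_interval_s * (1 + 1e-12))) + 1
    grid = traj.times_s[0] + frame_interval_s * np.arange(n_frames)
    positions = np.interp(grid, traj.times_s, traj.positions_um)
    return SampledTrack(
        track_id=track_id,
        frame_interval_s=float(frame_interval_s),
        times_s=grid - traj.times_s[0],
        positions_um=positions,
        provenance=provenance,
    )
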