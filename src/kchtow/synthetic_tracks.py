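"""Ground-truth synthetic tracks emulating tracked sperm-cell trajectories.

Raw in vivo tracks are not published, so the analysis stage is exercised
against synthetic tracks built from known piecewise-constant-velocity
segments: forward runs of ~10-15 nm/s lasting tens of seconds, slower
backward runs, and pauses, sampled at a uniform frame interval with
additive Gaussian localization noise — the structure a FIESTA-class
tracker reports for saltatory cargo motion.  Segment boundaries and
classes are returned as ground truth, so segmentation and statistics can
be validated exactly (noise-free) or calibrated (noisy).

Default cohort parameters follow the in vivo regime (forward
10.85 +/- 1.93 nm/s, backward -9.06 +/- 4.45 nm/s, run durations
44.89 +/- 39.69 s and 32.03 +/- 25.15 s); they describe realistic inputs,
not reproduction targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .gillespie import SampledTrack
from .track_analysis import PAUSE_THRESHOLD_NM_S

__all__ = ["SegmentSpec", "SyntheticCohortSpec", "make_track", "make_cohort"]


@dataclass(frozen=True)
class SegmentSpec:
    """One constant-velocity segment: class, duration (s) and velocity
    (nm/s; 0 for pauses, sign matching the class)."""

    cls: str
    duration_s: float
    velocity_nm_s: float

    def __post_init__(self) -> None:
        if self.cls not in ("forward", "backward", "pause"):
            raise ValueError(f"unknown segment class {self.cls!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        v = self.velocity_nm_s
        if self.cls == "pause" and v != 0:
            raise ValueError("pause segments have velocity 0")
        if self.cls == "forward" and v <= PAUSE_THRESHOLD_NM_S:
            raise ValueError("forward segment velocity must exceed the pause threshold")
        if self.cls == "backward" and v >= -PAUSE_THRESHOLD_NM_S:
            raise ValueError("backward segment velocity must fall below -threshold")


def make_track(
    segments: Sequence[SegmentSpec],
    frame_interval_s: float = 5.0,
    noise_sd_nm: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    track_id: str = "synth",
) -> tuple[SampledTrack, pd.DataFrame]:
    """Sample a piecewise-linear trajectory on a uniform grid.

    Gaussian localization noise of SD ``noise_sd_nm`` is added i.i.d. per
    frame.  Returns the track and a ground-truth run table (one row per
    segment: cls, t_start, t_end, duration_s, displacement_um,
    velocity_nm_s).
    """
    if not segments:
        raise ValueError("empty segment list")
    if frame_interval_s <= 0:
        raise ValueError("frame_interval_s must be > 0")
    total = sum(s.duration_s for s in segments)
    if total < 2 * frame_interval_s:
        raise ValueError("total duration must cover at least two frame intervals")
    if rng is None:
        rng = np.random.default_rng(seed)

    knots_t = np.concatenate([[0.0], np.cumsum([s.duration_s for s in segments])])
    knots_x = np.concatenate(
        [[0.0], np.cumsum([s.duration_s * s.velocity_nm_s / 1000.0 for s in segments])]
    )
    n_frames = int(math.floor(total / frame_interval_s * (1 + 1e-12))) + 1
    grid = frame_interval_s * np.arange(n_frames)
    positions = np.interp(grid, knots_t, knots_x)
    if noise_sd_nm > 0:
        positions = positions + rng.normal(0.0, noise_sd_nm / 1000.0, n_frames)

    truth = pd.DataFrame(
        {
            "cls": [s.cls for s in segments],
            "t_start": knots_t[:-1],
            "t_end": knots_t[1:],
            "duration_s": [s.duration_s for s in segments],
            "displacement_um": np.diff(knots_x),
            "velocity_nm_s": [s.velocity_nm_s for s in segments],
        }
    )
    track = SampledTrack(
        track_id=track_id,
        frame_interval_s=frame_interval_s,
        times_s=grid,
        positions_um=positions,
        provenance="synthetic",
    )
    return track, truth


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Distributional spec of a synthetic cohort.

    Velocities are (mean, SD) in nm/s (backward as magnitude), durations
    (mean, SD) in seconds.  Durations and speeds are drawn from truncated
    normals by default (``duration_family="truncnorm"``) — the published
    statistics give mean +/- SD only — with an exponential alternative for
    durations.  Truncation keeps durations >= one frame interval and
    speeds above the pause threshold.
    """

    n_tracks: int = 21
    track_duration_s: float = 3600.0
    frame_interval_s: float = 5.0
    forward_velocity_nm_s: tuple[float, float] = (10.85, 1.93)
    backward_velocity_nm_s: tuple[float, float] = (9.06, 4.45)
    forward_run_duration_s: tuple[float, float] = (44.89, 39.69)
    backward_run_duration_s: tuple[float, float] = (32.03, 25.15)
    pause_duration_s: tuple[float, float] = (25.0, 20.0)
    noise_sd_nm: float = 10.0
    duration_family: str = "truncnorm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be >= 1")
        if self.frame_interval_s <= 0 or self.track_duration_s <= 0:
            raise ValueError("durations must be > 0")
        if self.duration_family not in ("truncnorm", "exponential"):
            raise ValueError(f"unknown duration_family {self.duration_family!r}")
        for name in (
            "forward_velocity_nm_s",
            "backward_velocity_nm_s",
            "forward_run_duration_s",
            "backward_run_duration_s",
            "pause_duration_s",
        ):
            mean, sd = getattr(self, name)
            if mean <= 0 or sd < 0:
                raise ValueError(f"{name}: mean must be > 0 and SD >= 0")
        if self.noise_sd_nm < 0:
            raise ValueError("noise_sd_nm must be >= 0")


def _draw_truncated(
    rng: np.random.Generator, mean: float, sd: float, lower: float, family: str
) -> float:
    """One draw from a normal (or exponential) truncated at ``lower``."""
    if family == "exponential":
        # shifted exponential keeps the requested mean where possible
        scale = max(mean - lower, 1e-9)
        return lower + rng.exponential(scale)
    if sd == 0:
        if mean <= lower:
            raise ValueError(
                f"degenerate distribution at {mean} cannot satisfy bound > {lower}"
            )
        return mean
    a = (lower - mean) / sd
    if a > 6.0:  # essentially no mass above the bound
        raise ValueError(
            f"truncation bound {lower} is {a:.1f} SDs above the mean {mean}"
        )
    return float(sp_stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def make_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[list[SampledTrack], pd.DataFrame]:
    """Generate a cohort of alternating run/pause tracks.

    Each track cycles forward run, pause, backward run, pause, ... with
    durations and speeds drawn from the spec distributions until the track
    duration is filled (the last segment is clipped).  Returns the tracks
    and the concatenated ground-truth run table with a ``track_id`` column.
    """
    root = np.random.SeedSequence(spec.seed)
    tracks: list[SampledTrack] = []
    truths: list[pd.DataFrame] = []
    for i, child in enumerate(root.spawn(spec.n_tracks)):
        rng = np.random.default_rng(child)
        segments: list[SegmentSpec] = []
        total = 0.0
        cycle = ("forward", "pause", "backward", "pause")
        k = 0
        while total < spec.track_duration_s:
            cls = cycle[k % 4]
            k += 1
            if cls == "pause":
                dur = _draw_truncated(
                    rng, *spec.pause_duration_s, spec.frame_interval_s, spec.duration_family
                )
                v = 0.0
            else:
                mean_d, sd_d = (
                    spec.forward_run_duration_s
                    if cls == "forward"
                    else spec.backward_run_duration_s
                )
                dur = _draw_truncated(
                    rng, mean_d, sd_d, spec.frame_interval_s, spec.duration_family
                )
                mean_v, sd_v = (
                    spec.forward_velocity_nm_s
                    if cls == "forward"
                    else spec.backward_velocity_nm_s
                )
                speed = _draw_truncated(
                    rng, mean_v, sd_v, PAUSE_THRESHOLD_NM_S, "truncnorm"
                )
                v = speed if cls == "forward" else -speed
            dur = min(dur, spec.track_duration_s - total)
            if dur < spec.frame_interval_s / 100.0:
                break
            if cls != "pause" or dur > 0:
                segments.append(SegmentSpec(cls, dur, v))
            total += dur
        track_id = f"synth{i:03d}"
        track, truth = make_track(
            segments,
            frame_interval_s=spec.frame_interval_s,
            noise_sd_nm=spec.noise_sd_nm,
            rng=rng,
            track_id=track_id,
        )
        truth.insert(0, "track_id", track_id)
        tracks.append(track)
        truths.append(truth)
    return tracks, pd.concat(truths, ignore_index=True)
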