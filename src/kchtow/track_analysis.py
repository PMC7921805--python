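"""Run/pause segmentation and displacement-weighted velocity statistics.

The evaluation mirrors the procedure applied to in vivo tracked sperm
cells: point-to-point displacements between consecutive frames, a
1 nm/s velocity threshold separating movement from pauses, merging of
consecutive same-direction supra-threshold intervals into runs, a
displacement-weighted velocity histogram per direction with a Gaussian fit
whose mean and SD are the reported run velocities, and a paired cohort
comparison of forward versus backward statistics.

Positions stay in um; interval and run velocities are expressed in nm/s,
the scale of the threshold and of all reported values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gillespie import SampledTrack

__all__ = [
    "PAUSE_THRESHOLD_NM_S",
    "classify_velocity",
    "point_displacements",
    "segment_runs",
    "VelocityDistribution",
    "weighted_velocity_distribution",
    "TrackStats",
    "per_track_stats",
    "CohortStats",
    "cohort_compare",
]

#: Default pause threshold: intervals slower than 1 nm/s are pauses.
PAUSE_THRESHOLD_NM_S = 1.0


def classify_velocity(v_nm_s: float, threshold: float = PAUSE_THRESHOLD_NM_S) -> str:
    """Classify one interval velocity.  Ties (|v| exactly at the threshold)
    count as pauses, the deterministic reading of 'smaller than 1 nm/s'."""
    if v_nm_s > threshold:
        return "forward"
    if v_nm_s < -threshold:
        return "backward"
    return "pause"


def point_displacements(
    track: SampledTrack, threshold: float = PAUSE_THRESHOLD_NM_S
) -> pd.DataFrame:
    """Point-to-point displacements between consecutive frames.

    Returns one row per frame pair with columns ``t_start``, ``t_end``,
    ``dt_s``, ``dx_um`` (signed), ``v_nm_s`` (signed) and ``cls``
    (forward / backward / pause at ``threshold``).  The signed displacements
    telescope: their sum equals the end-to-end displacement exactly.
    """
    t = np.asarray(track.times_s, dtype=float)
    x = np.asarray(track.positions_um, dtype=float)
    if len(t) < 2:
        raise ValueError("track needs at least 2 frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("track times must be strictly increasing")
    dx = np.diff(x)
    v = dx / dt * 1000.0  # um/s -> nm/s
    cls = np.where(v > threshold, "forward", np.where(v < -threshold, "backward", "pause"))
    return pd.DataFrame(
        {
            "t_start": t[:-1],
            "t_end": t[1:],
            "dt_s": dt,
            "dx_um": dx,
            "v_nm_s": v,
            "cls": cls,
        }
    )


def segment_runs(
    intervals: pd.DataFrame,
    threshold: float = PAUSE_THRESHOLD_NM_S,
    min_intervals_per_run: int = 1,
) -> pd.DataFrame:
    """Merge consecutive same-class intervals into runs and pauses.

    Maximal blocks of consecutive intervals sharing a class become one run;
    the output tiles the track without gaps or overlaps and adjacent runs
    differ in class.  With ``min_intervals_per_run > 1`` (the stricter
    reading of the merging rule) directional blocks of fewer intervals are
    reclassified as pauses before the final merge, so no time is discarded.

    Columns: ``cls``, ``t_start``, ``t_end``, ``duration_s``,
    ``displacement_um``, ``n_intervals``, ``mean_v_nm_s`` (displacement /
    duration).
    """
    if len(intervals) == 0:
        raise ValueError("no intervals to segment")
    v = intervals["v_nm_s"].to_numpy()
    cls = np.where(v > threshold, "forward", np.where(v < -threshold, "backward", "pause"))

    def blocks(labels: np.ndarray) -> list[tuple[int, int, str]]:
        out = []
        start = 0
        for i in range(1, len(labels) + 1):
            if i == len(labels) or labels[i] != labels[start]:
                out.append((start, i, labels[start]))
                start = i
        return out

    if min_intervals_per_run > 1:
        for start, stop, label in blocks(cls):
            if label != "pause" and (stop - start) < min_intervals_per_run:
                cls[start:stop] = "pause"

    rows = []
    t_start = intervals["t_start"].to_numpy()
    t_end = intervals["t_end"].to_numpy()
    dx = intervals["dx_um"].to_numpy()
    dt = intervals["dt_s"].to_numpy()
    for start, stop, label in blocks(cls):
        duration = float(dt[start:stop].sum())
        disp = float(dx[start:stop].sum())
        rows.append(
            {
                "cls": label,
                "t_start": float(t_start[start]),
                "t_end": float(t_end[stop - 1]),
                "duration_s": duration,
                "displacement_um": disp,
                "n_intervals": stop - start,
                "mean_v_nm_s": disp / duration * 1000.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class VelocityDistribution:
    """Displacement-weighted velocity histogram of one direction class.

    Each interval contributes its absolute displacement ``|dx|`` as weight.
    ``fit_mean`` / ``fit_sd`` come from a least-squares Gaussian fit to the
    histogram when at least four bins are populated (``fit_ok``); otherwise
    they fall back to the displacement-weighted moments, which are always
    reported alongside.
    """

    direction: str
    bin_edges: np.ndarray
    weights: np.ndarray
    weighted_mean: float
    weighted_sd: float
    fit_mean: float
    fit_sd: float
    fit_ok: bool
    n_intervals: int

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def _gauss(v, amplitude, mu, sigma):
    return amplitude * np.exp(-((v - mu) ** 2) / (2.0 * sigma**2))


def weighted_velocity_distribution(
    intervals: pd.DataFrame,
    direction: str = "forward",
    bin_width: float = 1.0,
    threshold: float = PAUSE_THRESHOLD_NM_S,
) -> VelocityDistribution:
    """Histogram the interval velocities of one direction, weighting each
    interval by the distance moved in it, and fit a Gaussian.

    ``intervals`` may be the full interval table; rows are selected by sign
    against ``threshold``.  Requires at least one qualifying interval.
    """
    if direction not in ("forward", "backward"):
        raise ValueError(f"direction must be forward or backward, got {direction!r}")
    v_all = intervals["v_nm_s"].to_numpy()
    mask = v_all > threshold if direction == "forward" else v_all < -threshold
    if not mask.any():
        raise ValueError(f"no {direction} intervals above the threshold")
    v = v_all[mask]
    w = np.abs(intervals["dx_um"].to_numpy()[mask])

    wmean = float(np.average(v, weights=w))
    wvar = float(np.average((v - wmean) ** 2, weights=w))
    wsd = math.sqrt(wvar)

    lo = bin_width * math.floor(v.min() / bin_width)
    hi = bin_width * math.ceil(v.max() / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    weights, edges = np.histogram(v, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])

    fit_ok = False
    fit_mean, fit_sd = wmean, wsd
    if np.count_nonzero(weights) >= 4:
        # mean constrained to the histogram support and sigma to its width:
        # unbounded fits can run away on broad multimodal weighted histograms
        p0 = (
            float(weights.max()),
            min(max(wmean, lo), hi),
            min(max(wsd, bin_width), hi - lo),
        )
        try:
            popt, _ = optimize.curve_fit(
                _gauss,
                centers,
                weights,
                p0=p0,
                bounds=([0.0, lo, bin_width / 10.0], [np.inf, hi, (hi - lo) * 2.0]),
                maxfev=10000,
            )
            fit_mean, fit_sd = float(popt[1]), float(popt[2])
            fit_ok = True
        except (RuntimeError, ValueError):
            pass  # singular fit: weighted moments stand in, flagged by fit_ok

    return VelocityDistribution(
        direction=direction,
        bin_edges=edges,
        weights=weights,
        weighted_mean=wmean,
        weighted_sd=wsd,
        fit_mean=fit_mean,
        fit_sd=fit_sd,
        fit_ok=fit_ok,
        n_intervals=int(mask.sum()),
    )


@dataclass
class TrackStats:
    """Per-track summary.  Velocities are Gaussian-fit means in nm/s
    (backward stored signed, negative); run durations are means over runs in
    seconds.  Fields are None when the track has no run of that class."""

    track_id: str
    duration_s: float
    net_velocity_nm_s: float
    forward_velocity_nm_s: Optional[float]
    backward_velocity_nm_s: Optional[float]
    forward_run_duration_s: Optional[float]
    backward_run_duration_s: Optional[float]
    n_forward_runs: int
    n_backward_runs: int
    forward_fit_ok: bool = False
    backward_fit_ok: bool = False


def per_track_stats(
    track: SampledTrack,
    threshold: float = PAUSE_THRESHOLD_NM_S,
    bin_width: float = 1.0,
    min_intervals_per_run: int = 1,
) -> TrackStats:
    """Full single-track evaluation: displacements, segmentation, and the
    fitted forward/backward velocities and mean run durations."""
    intervals = point_displacements(track, threshold)
    runs = segment_runs(intervals, threshold, min_intervals_per_run)

    # velocity distributions are built from the intervals belonging to runs
    # of each class, so the stricter merging rule propagates consistently
    member = _run_membership(intervals, runs)
    stats_: dict[str, Optional[float]] = {}
    fit_flags = {}
    for direction in ("forward", "backward"):
        sel = intervals[member == direction]
        if len(sel) == 0:
            stats_[direction] = None
            fit_flags[direction] = False
            continue
        dist = weighted_velocity_distribution(sel, direction, bin_width, threshold)
        stats_[direction] = dist.fit_mean
        fit_flags[direction] = dist.fit_ok

    def mean_duration(direction: str) -> Optional[float]:
        sel = runs[runs["cls"] == direction]
        return float(sel["duration_s"].mean()) if len(sel) else None

    duration = track.duration_s
    net = (track.positions_um[-1] - track.positions_um[0]) / duration * 1000.0
    return TrackStats(
        track_id=track.track_id,
        duration_s=duration,
        net_velocity_nm_s=float(net),
        forward_velocity_nm_s=stats_["forward"],
        backward_velocity_nm_s=stats_["backward"],
        forward_run_duration_s=mean_duration("forward"),
        backward_run_duration_s=mean_duration("backward"),
        n_forward_runs=int((runs["cls"] == "forward").sum()),
        n_backward_runs=int((runs["cls"] == "backward").sum()),
        forward_fit_ok=fit_flags["forward"],
        backward_fit_ok=fit_flags["backward"],
    )


def _run_membership(intervals: pd.DataFrame, runs: pd.DataFrame) -> np.ndarray:
    """Label every interval with the class of the run containing it."""
    labels = np.empty(len(intervals), dtype=object)
    counts = runs["n_intervals"].to_numpy()
    classes = runs["cls"].to_numpy()
    pos = 0
    for count, cls in zip(counts, classes):
        labels[pos : pos + count] = cls
        pos += count
    return labels


@dataclass
class CohortStats:
    """Cohort-level summary: mean +/- SD of the per-track statistics over
    tracks where each is defined, and paired two-sided tests of forward vs
    backward magnitude across tracks with both directions present."""

    n_tracks: int
    n_paired: int
    forward_velocity_mean: float
    forward_velocity_sd: float
    backward_velocity_mean: float  # magnitude, nm/s
    backward_velocity_sd: float
    forward_run_duration_mean: float
    forward_run_duration_sd: float
    backward_run_duration_mean: float
    backward_run_duration_sd: float
    net_velocity_mean: float
    net_velocity_sd: float
    p_velocity: float
    p_run_duration: float
    test: str = "paired-t"


def cohort_compare(track_stats: Sequence[TrackStats], test: str = "t") -> CohortStats:
    """Compare forward and backward statistics across a cohort of tracks.

    ``test``: ``"t"`` for the paired two-sided t-test (default) or
    ``"wilcoxon"`` for the signed-rank alternative.  Backward velocities
    enter as magnitudes.  Requires at least 3 tracks with both directions.
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError(f"unknown test {test!r}")

    def column(getter) -> np.ndarray:
        return np.array([getter(s) for s in track_stats], dtype=float)

    fwd_v = column(lambda s: np.nan if s.forward_velocity_nm_s is None else s.forward_velocity_nm_s)
    bwd_v = column(
        lambda s: np.nan if s.backward_velocity_nm_s is None else abs(s.backward_velocity_nm_s)
    )
    fwd_d = column(
        lambda s: np.nan if s.forward_run_duration_s is None else s.forward_run_duration_s
    )
    bwd_d = column(
        lambda s: np.nan if s.backward_run_duration_s is None else s.backward_run_duration_s
    )
    net = column(lambda s: s.net_velocity_nm_s)

    paired = ~(np.isnan(fwd_v) | np.isnan(bwd_v) | np.isnan(fwd_d) | np.isnan(bwd_d))
    n_paired = int(paired.sum())
    if n_paired < 3:
        raise ValueError(f"need >= 3 tracks with both directions, got {n_paired}")

    if test == "t":
        p_v = float(stats.ttest_rel(fwd_v[paired], bwd_v[paired]).pvalue)
        p_d = float(stats.ttest_rel(fwd_d[paired], bwd_d[paired]).pvalue)
    else:
        p_v = float(stats.wilcoxon(fwd_v[paired], bwd_v[paired]).pvalue)
        p_d = float(stats.wilcoxon(fwd_d[paired], bwd_d[paired]).pvalue)

    def mean_sd(a: np.ndarray) -> tuple[float, float]:
        a = a[~np.isnan(a)]
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    fv_m, fv_s = mean_sd(fwd_v)
    bv_m, bv_s = mean_sd(bwd_v)
    fd_m, fd_s = mean_sd(fwd_d)
    bd_m, bd_s = mean_sd(bwd_d)
    nv_m, nv_s = mean_sd(net)
    return CohortStats(
        n_tracks=len(track_stats),
        n_paired=n_paired,
        forward_velocity_mean=fv_m,
        forward_velocity_sd=fv_s,
        backward_velocity_mean=bv_m,
        backward_velocity_sd=bv_s,
        forward_run_duration_mean=fd_m,
        forward_run_duration_sd=fd_s,
        backward_run_duration_mean=bd_m,
        backward_run_duration_sd=bd_s,
        net_velocity_mean=nv_m,
        net_velocity_sd=nv_s,
        p_velocity=p_v,
        p_run_duration=p_d,
        test="paired-t" if test == "t" else "wilcoxon",
    )
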