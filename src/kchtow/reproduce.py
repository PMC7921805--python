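"""Cohort-scale regeneration of the simulated study.

``reproduce_cohort`` runs the full pipeline — simulate 21 tracks of one
hour with the default parameters, downsample to the analysis frame
interval, segment and fit — and reports the cohort statistics next to the
published simulated-cohort values, together with a frame-interval
sensitivity table (the experimental frame rate was never published) and a
motor-number robustness sweep.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .gillespie import SampledTrack, downsample, simulate_cohort
from .motor_model import TugOfWarParams, default_params
from .track_analysis import (
    PAUSE_THRESHOLD_NM_S,
    CohortStats,
    TrackStats,
    cohort_compare,
    per_track_stats,
)

__all__ = ["REFERENCE_SIMULATED", "ReproduceReport", "analyze_cohort", "reproduce_cohort"]

#: Published simulated-cohort statistics (21 tracks), for side-by-side display
#: in the report only — never used in any computation.
REFERENCE_SIMULATED = {
    "forward_velocity_nm_s": (10.83, 0.76),
    "backward_velocity_nm_s": (6.77, 0.38),
    "forward_run_duration_s": (30.76, 1.66),
    "backward_run_duration_s": (25.91, 1.40),
}


def analyze_cohort(
    tracks: Sequence[SampledTrack],
    threshold: float = PAUSE_THRESHOLD_NM_S,
    bin_width: float = 1.0,
    min_intervals_per_run: int = 1,
    test: str = "t",
) -> tuple[list[TrackStats], CohortStats]:
    """Per-track statistics and cohort comparison for any track list; the
    single code path shared by simulated, synthetic and experimental data."""
    stats = [
        per_track_stats(t, threshold, bin_width, min_intervals_per_run) for t in tracks
    ]
    return stats, cohort_compare(stats, test=test)


@dataclass
class ReproduceReport:
    """Everything one reproduction run computed, JSON-serializable."""

    config: dict
    cohort: CohortStats
    track_stats: list[TrackStats]
    reference: dict
    dt_sensitivity: dict[float, dict]
    motor_sweep: dict[int, dict]
    elapsed_s: float

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "cohort": dataclasses.asdict(self.cohort),
            "track_stats": [dataclasses.asdict(s) for s in self.track_stats],
            "reference": {k: list(v) for k, v in self.reference.items()},
            "dt_sensitivity": {str(k): v for k, v in self.dt_sensitivity.items()},
            "motor_sweep": {str(k): v for k, v in self.motor_sweep.items()},
            "elapsed_s": self.elapsed_s,
        }

    def summary_lines(self) -> list[str]:
        c = self.cohort
        ref = self.reference
        rows = [
            ("forward velocity [nm/s]", c.forward_velocity_mean, c.forward_velocity_sd,
             ref["forward_velocity_nm_s"]),
            ("backward velocity [nm/s]", c.backward_velocity_mean, c.backward_velocity_sd,
             ref["backward_velocity_nm_s"]),
            ("forward run duration [s]", c.forward_run_duration_mean,
             c.forward_run_duration_sd, ref["forward_run_duration_s"]),
            ("backward run duration [s]", c.backward_run_duration_mean,
             c.backward_run_duration_sd, ref["backward_run_duration_s"]),
        ]
        lines = [f"simulated cohort, n={c.n_tracks} tracks ({self.config['duration_s']} s, "
                 f"dt={self.config['frame_interval_s']} s, N={self.config['n_motors']})"]
        lines.append(f"{'quantity':28s} {'this run':>16s} {'published':>16s}")
        for name, mean, sd, (rmean, rsd) in rows:
            lines.append(f"{name:28s} {mean:8.2f} ± {sd:5.2f} {rmean:8.2f} ± {rsd:5.2f}")
        lines.append(
            f"paired t ({c.n_paired} tracks): p_velocity={c.p_velocity:.2e}, "
            f"p_run_duration={c.p_run_duration:.2e}"
        )
        lines.append(f"net velocity {c.net_velocity_mean:.2f} ± {c.net_velocity_sd:.2f} nm/s")
        return lines


def _cohort_summary(cs: CohortStats) -> dict:
    return {
        "forward_velocity_nm_s": cs.forward_velocity_mean,
        "backward_velocity_nm_s": cs.backward_velocity_mean,
        "forward_run_duration_s": cs.forward_run_duration_mean,
        "backward_run_duration_s": cs.backward_run_duration_mean,
        "net_velocity_nm_s": cs.net_velocity_mean,
        "p_velocity": cs.p_velocity,
        "p_run_duration": cs.p_run_duration,
        "n_paired": cs.n_paired,
    }


def reproduce_cohort(
    params: Optional[TugOfWarParams] = None,
    n_tracks: int = 21,
    duration_s: float = 3600.0,
    frame_interval_s: float = 5.0,
    seed: int = 0,
    threshold: float = PAUSE_THRESHOLD_NM_S,
    bin_width: float = 1.0,
    min_intervals_per_run: int = 1,
    dt_sensitivity: Sequence[float] = (2.0, 5.0, 10.0),
    motor_numbers: Sequence[int] = (30, 50, 70, 100),
    sweep_tracks: int = 7,
    test: str = "t",
) -> ReproduceReport:
    """Simulate and evaluate the model cohort.

    The same event trajectories are re-downsampled at every requested frame
    interval, so the sensitivity table isolates the evaluation step.  The
    motor sweep runs ``sweep_tracks`` fresh tracks per motor number (seeded
    independently per N) and reports direction-resolved summaries plus the
    fraction of tracks with positive net displacement.
    """
    t0 = time.time()
    if params is None:
        params = default_params()
    config = {
        **params.to_dict(),
        "n_tracks": n_tracks,
        "duration_s": duration_s,
        "frame_interval_s": frame_interval_s,
        "seed": seed,
        "threshold_nm_s": threshold,
        "bin_width_nm_s": bin_width,
        "min_intervals_per_run": min_intervals_per_run,
        "test": test,
    }

    dts = list(dict.fromkeys([frame_interval_s, *dt_sensitivity]))
    per_dt_tracks: dict[float, list[SampledTrack]] = {dt: [] for dt in dts}
    for i, traj in enumerate(simulate_cohort(params, n_tracks, duration_s, seed)):
        for dt in dts:
            per_dt_tracks[dt].append(downsample(traj, dt, track_id=f"sim{i:03d}"))

    track_stats, cohort = analyze_cohort(
        per_dt_tracks[frame_interval_s], threshold, bin_width, min_intervals_per_run, test
    )

    sensitivity = {}
    for dt in dts:
        _, cs = analyze_cohort(
            per_dt_tracks[dt], threshold, bin_width, min_intervals_per_run, test
        )
        sensitivity[dt] = _cohort_summary(cs)

    sweep = {}
    for n_motors in motor_numbers:
        p_n = params.with_n_motors(n_motors)
        stats_n = []
        # offset the seed stream per N so sweep cohorts are independent
        for i, traj in enumerate(
            simulate_cohort(p_n, sweep_tracks, duration_s, seed + 1000 + n_motors)
        ):
            st = downsample(traj, frame_interval_s, track_id=f"N{n_motors}_{i:02d}")
            stats_n.append(per_track_stats(st, threshold, bin_width, min_intervals_per_run))
        net = np.array([s.net_velocity_nm_s for s in stats_n])
        fwd = np.array(
            [s.forward_velocity_nm_s for s in stats_n if s.forward_velocity_nm_s is not None]
        )
        bwd = np.array(
            [
                abs(s.backward_velocity_nm_s)
                for s in stats_n
                if s.backward_velocity_nm_s is not None
            ]
        )
        sweep[n_motors] = {
            "n_tracks": sweep_tracks,
            "net_velocity_nm_s_mean": float(net.mean()),
            "fraction_net_positive": float((net > 0).mean()),
            "forward_velocity_nm_s_mean": float(fwd.mean()) if len(fwd) else None,
            "backward_velocity_nm_s_mean": float(bwd.mean()) if len(bwd) else None,
        }

    return ReproduceReport(
        config=config,
        cohort=cohort,
        track_stats=track_stats,
        reference=dict(REFERENCE_SIMULATED),
        dt_sensitivity=sensitivity,
        motor_sweep=sweep,
        elapsed_s=time.time() - t0,
    )
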