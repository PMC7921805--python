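"""Track, statistics and configuration file plumbing.

Tracks travel as tidy CSV with columns ``track_id, time_s, position_um``
(multiple tracks per file, keyed by ``track_id``); configurations as flat
YAML whose keys mirror the model parameter names one-to-one
(``forward_stall_force_pN`` etc.).  Round trips are lossless to well below
1e-9 um.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .gillespie import SampledTrack
from .motor_model import TugOfWarParams, default_params
from .track_analysis import CohortStats, TrackStats

__all__ = [
    "read_tracks",
    "write_tracks",
    "write_stats",
    "write_runs",
    "load_config",
    "save_config",
    "params_from_config",
]

_COLUMNS = ("track_id", "time_s", "position_um")


def write_tracks(tracks: Sequence[SampledTrack], path: Union[str, Path]) -> None:
    """Write a cohort to tidy CSV, full float precision."""
    frames = [
        pd.DataFrame(
            {"track_id": t.track_id, "time_s": t.times_s, "position_um": t.positions_um}
        )
        for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_tracks(path: Union[str, Path]) -> list[SampledTrack]:
    """Read a track CSV back into :class:`SampledTrack` objects.

    Tracks are keyed by ``track_id`` (block order in the file is
    irrelevant).  Malformed rows and non-increasing times are reported with
    1-based data line numbers.  Provenance is marked ``experimental``: the
    file format carries none and analysis treats all provenances alike.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"track_id": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty input file") from None
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}; expected {list(_COLUMNS)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("time_s", "position_um"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise ValueError(f"{path}: non-numeric {col} at line(s) {lines}")
        df[col] = numeric

    tracks = []
    for track_id, group in df.groupby("track_id", sort=True):
        t = group["time_s"].to_numpy()
        x = group["position_um"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"{path}: track {track_id!r} has fewer than 2 frames")
        dt = np.diff(t)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            line = int(group.index[i + 1]) + 2
            raise ValueError(
                f"{path}: non-increasing time in track {track_id!r} at line {line}"
            )
        tracks.append(
            SampledTrack(
                track_id=str(track_id),
                frame_interval_s=float(np.median(dt)),
                times_s=t,
                positions_um=x,
                provenance="experimental",
            )
        )
    return tracks


def write_stats(
    track_stats: Sequence[TrackStats],
    cohort: CohortStats,
    out_dir: Union[str, Path],
    config: dict | None = None,
) -> None:
    """Write the per-track table (`track_stats.csv`), the cohort summary
    (`cohort_summary.json`) and, when given, the resolved configuration."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(s) for s in track_stats]).to_csv(
        out_dir / "track_stats.csv", index=False, float_format="%.12g"
    )
    summary = dataclasses.asdict(cohort)
    if config is not None:
        summary["config"] = config
    (out_dir / "cohort_summary.json").write_text(json.dumps(summary, indent=2))


def write_runs(runs: pd.DataFrame, path: Union[str, Path]) -> None:
    """Export a run segmentation (one row per run)."""
    runs.to_csv(path, index=False, float_format="%.12g")


def load_config(path: Union[str, Path]) -> dict:
    """Load a flat YAML config; model parameters under their flat keys, plus
    any of duration_s, frame_interval_s, n_tracks, seed, threshold_nm_s."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def params_from_config(cfg: dict) -> TugOfWarParams:
    """Build model parameters from a flat config dict, falling back to the
    default parameter set for absent keys."""
    base = default_params().to_dict()
    known = set(base)
    base.update({k: v for k, v in cfg.items() if k in known})
    return TugOfWarParams.from_dict(base)
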