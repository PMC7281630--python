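"""File formats: trajectory CSVs, frame stacks, result tables, configs.

Track CSV schema (one row per frame, long format)::

    sample_id, rep_index, t_s, y_um[, r_um]

Regression CSV::

    sample_id, rep_index, vT_um_s, intercept_um, r2, n_frames, max_r_um, accepted

Results CSV: one row per sample with all means/SDs, counts and flags.
All physical columns carry their unit in the column name so a table can
never be mis-read silently.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .cohort import CohortTable, SampleMeasurement
from .detect import FrameDetection, FrameStack, detections_table
from .errors import SchemaError
from .track import RepetitionResult, RepetitionTrack

__all__ = [
    "read_tracks_csv",
    "write_tracks_csv",
    "read_stack",
    "write_stack_tiff",
    "write_detections_csv",
    "write_regression_csv",
    "write_results_csv",
    "write_summary_json",
]

TRACK_COLUMNS = ("sample_id", "rep_index", "t_s", "y_um")


def read_tracks_csv(path: str | Path) -> list[RepetitionTrack]:
    """Load repetition tracks from a long-format CSV.

    Required columns: sample_id, rep_index, t_s, y_um; optional: r_um.
    Raises :class:`SchemaError` naming any missing column.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"track CSV {path} is missing column(s): {', '.join(missing)}")
    has_r = "r_um" in df.columns
    tracks = []
    for (sid, rep), grp in df.groupby(["sample_id", "rep_index"], sort=True):
        grp = grp.sort_values("t_s")
        tracks.append(
            RepetitionTrack(
                sample_id=str(sid),
                repetition_index=int(rep),
                times_s=grp["t_s"].to_numpy(float),
                y_um=grp["y_um"].to_numpy(float),
                radii_um=grp["r_um"].to_numpy(float) if has_r else None,
            )
        )
    return tracks


def write_tracks_csv(tracks: Sequence[RepetitionTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        radii = tr.radii_um if tr.radii_um is not None else [math.nan] * len(tr)
        for t, y, r in zip(tr.times_s, tr.y_um, radii):
            rows.append(
                {
                    "sample_id": tr.sample_id,
                    "rep_index": tr.repetition_index,
                    "t_s": t,
                    "y_um": y,
                    "r_um": r,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_stack(
    path: str | Path,
    frame_interval_s: float = 0.1,
    pixel_size_um: float = 1.0,
) -> FrameStack:
    """Read a multi-page TIFF (or a directory of numbered PNG/TIFF files).

    Timestamps are ``i * frame_interval_s``; the pixel size comes from a
    prior calibration.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        frames = np.stack([np.asarray(iio.imread(f), dtype=float) for f in files])
    else:
        frames = np.asarray(tifffile.imread(path), dtype=float)
        if frames.ndim == 2:
            frames = frames[None]
    times = np.arange(len(frames)) * frame_interval_s
    return FrameStack(frames=frames, timestamps_s=times, pixel_size_um=pixel_size_um,
                      metadata={"source": str(path)})


def write_stack_tiff(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as a float32 multi-page TIFF."""
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")


def write_detections_csv(
    detections: Sequence[FrameDetection], path: str | Path, timestamps_s=None
) -> None:
    pd.DataFrame(detections_table(detections, timestamps_s)).to_csv(path, index=False)


def write_regression_csv(results: Sequence[RepetitionResult], path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "rep_index": r.repetition_index,
            "vT_um_s": r.terminal_velocity_um_s,
            "intercept_um": r.intercept_um,
            "r2": r.r_squared,
            "n_frames": r.n_frames,
            "max_r_um": r.max_radius_um,
            "accepted": r.accepted,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_csv(
    table: CohortTable, path: str | Path, removal_reasons: dict[str, list[str]] | None = None
) -> None:
    """One row per sample: aggregates, counts, validity and retention."""
    reasons = removal_reasons if removal_reasons is not None else table.removal_reasons()
    retained = set(table.retained_ids)
    rows = []
    for s in table.samples:
        if not s.valid:
            reason = s.invalid_reason or "invalid"
        elif s.sample_id in retained:
            reason = ""
        else:
            reason = "tukey:" + "+".join(reasons.get(s.sample_id, ["?"]))
        rows.append(
            {
                "sample_id": s.sample_id,
                "final_radius_um": s.final_radius_um,
                "radius_sd_um": s.radius_sd_um,
                "diameter_um": s.diameter_um,
                "vT_mean_um_s": s.vt_mean_um_s,
                "vT_sd_um_s": s.vt_sd_um_s,
                "density_mean_fg_um3": s.density_mean_fg_um3,
                "density_sd_fg_um3": s.density_sd_fg_um3,
                "weight_mean_ng": s.weight_mean_ng,
                "weight_sd_ng": s.weight_sd_ng,
                "n_reps_total": s.n_repetitions_total,
                "n_reps_accepted": s.n_repetitions_accepted,
                "valid": s.valid,
                "retained": s.sample_id in retained,
                "removal_reason": reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_long_metrics_csv(table: CohortTable, path: str | Path) -> None:
    """Box-plot-ready long format: sample_id, metric, value, retained."""
    retained = set(table.retained_ids)
    rows = []
    for s in table.valid_samples:
        for metric in ("terminal_velocity", "mass_density", "diameter", "weight"):
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "metric": metric,
                    "value": s.metric(metric),
                    "retained": s.sample_id in retained,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(summary), indent=2, sort_keys=True) + "\n")
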