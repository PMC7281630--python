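"""Run configuration and end-to-end orchestration.

The pipeline chains the protocol stages: detect (if the input is images)
→ per-repetition regression with the R² screen → per-sample aggregation
with the minimum-accepted-repetitions gate → cohort outlier screen →
summary.  Every sample or repetition that drops out is attributed to
exactly one named rule (``min-frames``, ``r-squared``, ``rising``,
``five-of-nine``, ``tukey:<metric>``) in the run log, and every run
writes its resolved configuration next to its outputs so it can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import io as sfio
from .cohort import (
    CohortTable,
    aggregate_sample,
    screen_cohort,
    summarize_cohort,
)
from .core import MediumState, PhysicsConstants
from .detect import FrameStack, detect_stack
from .errors import (
    DegenerateTrackError,
    InsufficientDataError,
    InvalidParameterError,
    RisingSampleError,
    TooFewFramesError,
)
from .track import (
    RepetitionResult,
    RepetitionTrack,
    fit_terminal_velocity,
    track_from_detections,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """All protocol constants of a run, with units in the key names."""

    viscosity_mpa_s: float = 1.0
    medium_density_fg_um3: float = 1000.0
    temperature_c: float | None = None
    g_m_s2: float = 9.80665
    frame_interval_s: float = 0.1
    pixel_size_um: float = 1.0
    r2_threshold: float = 0.9999
    min_frames: int = 10
    repetitions_per_sample: int = 9
    min_accepted_repetitions: int = 5
    tukey_k: float = 1.5
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.r2_threshold <= 1:
            raise InvalidParameterError("r2_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.min_frames < 2:
            raise InvalidParameterError("min_frames must be >= 2")
        if self.min_accepted_repetitions < 1:
            raise InvalidParameterError("min_accepted_repetitions must be >= 1")
        if self.tukey_k < 0:
            raise InvalidParameterError("tukey_k must be >= 0")
        if not self.frame_interval_s > 0:
            raise InvalidParameterError("frame_interval_s must be > 0")
        if not self.pixel_size_um > 0:
            raise InvalidParameterError("pixel_size_um must be > 0")
        # constructing these validates viscosity / density / g
        self.medium
        self.constants

    @property
    def medium(self) -> MediumState:
        return MediumState(self.viscosity_mpa_s, self.medium_density_fg_um3, self.temperature_c)

    @property
    def constants(self) -> PhysicsConstants:
        return PhysicsConstants(self.g_m_s2)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True, default_flow_style=False)
        )


@dataclass
class PipelineResult:
    """Everything one run produced, plus the filter-stage bookkeeping."""

    table: CohortTable
    summary: dict
    regressions: list[RepetitionResult]
    rejected: list[dict] = field(default_factory=list)
    log_lines: list[str] = field(default_factory=list)


def _fit_tracks(
    tracks: Sequence[RepetitionTrack], config: RunConfig
) -> tuple[list[RepetitionResult], list[dict], list[str]]:
    results, rejected, log = [], [], []
    for tr in tracks:
        try:
            res = fit_terminal_velocity(tr, config.min_frames, config.r2_threshold)
        except TooFewFramesError:
            rejected.append(
                {"sample_id": tr.sample_id, "rep_index": tr.repetition_index, "rule": "min-frames"}
            )
            continue
        except (RisingSampleError, DegenerateTrackError) as exc:
            rule = "rising" if isinstance(exc, RisingSampleError) else "degenerate"
            rejected.append(
                {"sample_id": tr.sample_id, "rep_index": tr.repetition_index, "rule": rule}
            )
            continue
        results.append(res)
        if not res.accepted:
            rejected.append(
                {"sample_id": tr.sample_id, "rep_index": tr.repetition_index, "rule": "r-squared"}
            )
    for rej in rejected:
        log.append(
            f"repetition {rej['sample_id']}/{rej['rep_index']} rejected by rule {rej['rule']}"
        )
    return results, rejected, log


def run_pipeline(
    config: RunConfig,
    tracks: Sequence[RepetitionTrack] | None = None,
    stacks: Sequence[FrameStack] | None = None,
    stack_ids: Sequence[tuple[str, int]] | None = None,
    output_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the full analysis on tracks and/or frame stacks.

    ``stacks`` are detected first and become tracks (``stack_ids`` gives
    each stack its (sample_id, rep_index); defaults to the stack
    metadata).  Writes, when ``output_dir`` is given: regression CSV,
    per-sample results CSV, long-format metrics CSV, cohort summary
    JSON, the resolved config, and a plain-text log.
    """
    all_tracks: list[RepetitionTrack] = list(tracks) if tracks else []
    log: list[str] = []
    dropped_frames = 0
    if stacks:
        for i, stack in enumerate(stacks):
            if stack_ids is not None:
                sid, rep = stack_ids[i]
            else:
                sid = stack.metadata.get("sample_id", f"stack{i}")
                rep = stack.metadata.get("repetition_index", 0)
            detections = detect_stack(stack)
            n_bad = sum(1 for d in detections if not d.ok)
            dropped_frames += n_bad
            all_tracks.append(
                track_from_detections(detections, stack.timestamps_s, str(sid), int(rep))
            )
    if not all_tracks:
        raise InsufficientDataError("no input tracks or stacks")
    log.append(f"{len(all_tracks)} repetition tracks in, {dropped_frames} frames dropped")

    results, rejected, fit_log = _fit_tracks(all_tracks, config)
    log.extend(fit_log)

    by_sample: dict[str, list[RepetitionResult]] = {}
    for res in results:
        by_sample.setdefault(res.sample_id, []).append(res)
    measurements = []
    for sid in sorted(by_sample):
        m = aggregate_sample(
            by_sample[sid],
            config.medium,
            config.constants,
            min_accepted=config.min_accepted_repetitions,
        )
        if not m.valid:
            rejected.append({"sample_id": sid, "rep_index": None, "rule": "five-of-nine"})
            log.append(f"sample {sid} gated by rule five-of-nine ({m.invalid_reason})")
        measurements.append(m)

    n_valid = sum(1 for m in measurements if m.valid)
    if n_valid >= 4:
        table = screen_cohort(measurements, k=config.tukey_k, alpha=config.alpha)
    else:
        # too few samples for a meaningful box-plot screen: retain all valid
        table = CohortTable(samples=measurements)
        table.retained_ids = [m.sample_id for m in measurements if m.valid]
        log.append(f"cohort screen skipped: only {n_valid} valid samples (< 4)")
    for sid, metrics in table.removal_reasons().items():
        for metric in metrics:
            rejected.append({"sample_id": sid, "rep_index": None, "rule": f"tukey:{metric}"})
        log.append(f"sample {sid} removed by rule tukey:{'+'.join(metrics)}")
    log.append(
        f"{len(table.retained_ids)} samples retained, {len(table.removed_ids)} removed, "
        f"{sum(1 for m in measurements if not m.valid)} gated"
    )
    summary = summarize_cohort(table)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        sfio.write_regression_csv(results, out / "regressions.csv")
        sfio.write_results_csv(table, out / "results.csv")
        sfio.write_long_metrics_csv(table, out / "metrics_long.csv")
        sfio.write_summary_json(summary, out / "summary.json")
        config.to_yaml(out / "config_resolved.yaml")
        (out / "run.log").write_text("\n".join(log) + "\n")

    return PipelineResult(
        table=table, summary=summary, regressions=results, rejected=rejected, log_lines=log
    )
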