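"""Per-sample aggregation and cohort-level statistical screening.

A sample is measured over several repetitions.  Repetitions that survive
the R² screen contribute to:

* the *final radius*: mean of the per-repetition maximum radii;
* a mass density per repetition, from that repetition's terminal velocity
  and the sample's final radius via the inverted Stokes relation;
* a weight per repetition, ``W = rho V`` at the final radius.

A sample is valid only if at least ``min_accepted`` repetitions (default
5, of the canonical 9) pass the screen.

The cohort screen then works metric-wise on four outputs — terminal
velocity, mass density, diameter, weight: a Shapiro–Wilk normality test
per metric, Tukey box-plot fences (k = 1.5, quartiles by linear
interpolation of order statistics) on the metrics judged non-normal, and
removal of every sample flagged in at least one metric.  Normality is
re-tested once on the retained set; the screen is a single pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import (
    DEFAULT_CONSTANTS,
    MediumState,
    PhysicsConstants,
    density_from_terminal_velocity,
    weight_ng,
)
from .errors import DegenerateDataError, InsufficientDataError, InvalidParameterError
from .track import RepetitionResult

__all__ = [
    "SampleMeasurement",
    "NormalityReport",
    "CohortTable",
    "METRICS",
    "aggregate_sample",
    "shapiro_wilk",
    "tukey_outliers",
    "screen_cohort",
    "summarize_cohort",
]

#: the four screened output metrics, in reporting order
METRICS = ("terminal_velocity", "mass_density", "diameter", "weight")

DEFAULT_MIN_ACCEPTED = 5


@dataclass(frozen=True)
class SampleMeasurement:
    """Aggregate measurement of one sample over its accepted repetitions."""

    sample_id: str
    final_radius_um: float = math.nan
    radius_sd_um: float = math.nan
    vt_mean_um_s: float = math.nan
    vt_sd_um_s: float = math.nan
    density_mean_fg_um3: float = math.nan
    density_sd_fg_um3: float = math.nan
    weight_mean_ng: float = math.nan
    weight_sd_ng: float = math.nan
    n_repetitions_total: int = 0
    n_repetitions_accepted: int = 0
    valid: bool = False
    invalid_reason: str | None = None

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.final_radius_um

    @property
    def diameter_sd_um(self) -> float:
        return 2.0 * self.radius_sd_um

    def metric(self, name: str) -> float:
        """Value of one of the four screened metrics."""
        return {
            "terminal_velocity": self.vt_mean_um_s,
            "mass_density": self.density_mean_fg_um3,
            "diameter": self.diameter_um,
            "weight": self.weight_mean_ng,
        }[name]


@dataclass(frozen=True)
class NormalityReport:
    """Shapiro–Wilk result for one metric."""

    metric: str
    statistic_w: float
    p_value: float
    n: int
    alpha: float
    normal: bool


@dataclass
class CohortTable:
    """Screened cohort: samples, flags, verdicts, retained/removed sets."""

    samples: list[SampleMeasurement]
    outlier_flags: dict[str, dict[str, bool]] = field(default_factory=dict)
    normality_before: dict[str, NormalityReport] = field(default_factory=dict)
    normality_after: dict[str, NormalityReport | None] = field(default_factory=dict)
    retained_ids: list[str] = field(default_factory=list)
    removed_ids: list[str] = field(default_factory=list)

    @property
    def valid_samples(self) -> list[SampleMeasurement]:
        return [s for s in self.samples if s.valid]

    @property
    def retained(self) -> list[SampleMeasurement]:
        keep = set(self.retained_ids)
        return [s for s in self.samples if s.sample_id in keep]

    def removal_reasons(self) -> dict[str, list[str]]:
        """sample_id → list of metrics that flagged it."""
        reasons: dict[str, list[str]] = {}
        for metric, flags in self.outlier_flags.items():
            for sid, flagged in flags.items():
                if flagged:
                    reasons.setdefault(sid, []).append(metric)
        return reasons


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return math.nan, math.nan
    if np.ptp(values) == 0:  # identical values: mean exact, spread exactly zero
        return float(values[0]), 0.0 if values.size > 1 else math.nan
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else math.nan
    return mean, sd


def aggregate_sample(
    repetitions: Sequence[RepetitionResult],
    medium: MediumState,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
    min_accepted: int = DEFAULT_MIN_ACCEPTED,
    radius_mode: str = "sample",
) -> SampleMeasurement:
    """Aggregate one sample's repetitions into a SampleMeasurement.

    ``radius_mode='sample'`` (default) evaluates every repetition's density
    at the sample-level final radius — there is one final radius per
    sample.  ``radius_mode='repetition'`` uses each repetition's own
    maximum radius instead, for sensitivity analysis.
    """
    if not repetitions:
        raise InsufficientDataError("no repetitions supplied")
    if radius_mode not in ("sample", "repetition"):
        raise InvalidParameterError(f"unknown radius_mode {radius_mode!r}")
    ids = {r.sample_id for r in repetitions}
    if len(ids) != 1:
        raise InvalidParameterError(f"repetitions from multiple samples: {sorted(ids)}")
    sample_id = repetitions[0].sample_id
    accepted = [r for r in repetitions if r.accepted]
    n_total, n_acc = len(repetitions), len(accepted)
    if n_acc == 0:
        return SampleMeasurement(
            sample_id=sample_id,
            n_repetitions_total=n_total,
            valid=False,
            invalid_reason="no accepted repetitions",
        )

    max_radii = np.array([r.max_radius_um for r in accepted], dtype=float)
    if np.any(~np.isfinite(max_radii)):
        raise InvalidParameterError("accepted repetitions lack radii")
    final_radius, radius_sd = _mean_sd(max_radii)

    vts = np.array([r.terminal_velocity_um_s for r in accepted], dtype=float)
    radii_for_density = max_radii if radius_mode == "repetition" else np.full_like(vts, final_radius)
    densities = np.array(
        [
            density_from_terminal_velocity(vt, r, medium, constants)
            for vt, r in zip(vts, radii_for_density)
        ]
    )
    weights = np.array(
        [weight_ng(rho, r) for rho, r in zip(densities, radii_for_density)]
    )

    vt_mean, vt_sd = _mean_sd(vts)
    rho_mean, rho_sd = _mean_sd(densities)
    w_mean, w_sd = _mean_sd(weights)
    valid = n_acc >= min_accepted
    return SampleMeasurement(
        sample_id=sample_id,
        final_radius_um=final_radius,
        radius_sd_um=radius_sd,
        vt_mean_um_s=vt_mean,
        vt_sd_um_s=vt_sd,
        density_mean_fg_um3=rho_mean,
        density_sd_fg_um3=rho_sd,
        weight_mean_ng=w_mean,
        weight_sd_ng=w_sd,
        n_repetitions_total=n_total,
        n_repetitions_accepted=n_acc,
        valid=valid,
        invalid_reason=None if valid else f"only {n_acc} accepted repetitions < {min_accepted}",
    )


def shapiro_wilk(
    values: Iterable[float], alpha: float = 0.05, metric: str = ""
) -> NormalityReport:
    """Shapiro–Wilk normality test with a verdict at significance ``alpha``."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise InsufficientDataError(f"Shapiro–Wilk needs n >= 3, got {v.size}")
    if np.ptp(v) == 0:
        raise DegenerateDataError("all values identical: normality undefined")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must be in (0, 1)")
    w, p = stats.shapiro(v)
    return NormalityReport(
        metric=metric,
        statistic_w=float(w),
        p_value=float(p),
        n=int(v.size),
        alpha=alpha,
        normal=bool(p >= alpha),
    )


def tukey_outliers(values: Iterable[float], k: float = 1.5) -> np.ndarray:
    """Boolean flags for values outside the Tukey box-plot fences.

    Fences are ``[Q1 - k*IQR, Q3 + k*IQR]`` with quartiles computed by
    linear interpolation of order statistics.  With all values equal the
    IQR is zero and nothing is flagged.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 4:
        raise InsufficientDataError(f"Tukey fences need n >= 4, got {v.size}")
    if k < 0:
        raise InvalidParameterError("fence multiplier k must be >= 0")
    q1, q3 = np.percentile(v, [25.0, 75.0], method="linear")
    iqr = q3 - q1
    return (v < q1 - k * iqr) | (v > q3 + k * iqr)


def screen_cohort(
    samples: Sequence[SampleMeasurement] | CohortTable,
    metrics: Sequence[str] = METRICS,
    k: float = 1.5,
    alpha: float = 0.05,
    tukey_on: str = "non_normal",
) -> CohortTable:
    """One-pass outlier screen over the cohort's four output metrics.

    Per metric: Shapiro–Wilk verdict; Tukey fences on metrics with a
    non-normal verdict (``tukey_on='all'`` screens every metric instead).
    A sample flagged in at least one screened metric is removed.
    Normality is then re-tested once on the retained samples; a re-test
    that cannot run (too few or constant values) is recorded as None.
    """
    if isinstance(samples, CohortTable):
        samples = samples.samples
    if tukey_on not in ("non_normal", "all"):
        raise InvalidParameterError(f"unknown tukey_on {tukey_on!r}")
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise InvalidParameterError(f"unknown metrics: {sorted(unknown)}")
    valid = [s for s in samples if s.valid]
    if len(valid) < 4:
        raise InsufficientDataError(f"cohort screen needs >= 4 valid samples, got {len(valid)}")

    table = CohortTable(samples=list(samples))
    flagged: set[str] = set()
    for metric in metrics:
        vals = np.array([s.metric(metric) for s in valid])
        report = shapiro_wilk(vals, alpha=alpha, metric=metric)
        table.normality_before[metric] = report
        if tukey_on == "all" or not report.normal:
            flags = tukey_outliers(vals, k=k)
            table.outlier_flags[metric] = {
                s.sample_id: bool(f) for s, f in zip(valid, flags)
            }
            flagged.update(s.sample_id for s, f in zip(valid, flags) if f)
    table.removed_ids = sorted(flagged)
    table.retained_ids = [s.sample_id for s in valid if s.sample_id not in flagged]

    retained = [s for s in valid if s.sample_id not in flagged]
    for metric in metrics:
        try:
            table.normality_after[metric] = shapiro_wilk(
                [s.metric(metric) for s in retained], alpha=alpha, metric=metric
            )
        except (InsufficientDataError, DegenerateDataError):
            table.normality_after[metric] = None
    return table


_METRIC_FIELDS = {
    "terminal_velocity": ("vt_mean_um_s", "vt_sd_um_s"),
    "mass_density": ("density_mean_fg_um3", "density_sd_fg_um3"),
    "diameter": ("diameter_um", "diameter_sd_um"),
    "weight": ("weight_mean_ng", "weight_sd_ng"),
}


def summarize_cohort(table: CohortTable) -> dict:
    """Mean ± SD summary of the retained cohort, per metric.

    For each metric: the sample with the smallest and with the largest
    mean (each reported as its own mean ± SD over repetitions) and the
    cohort-level mean ± SD across retained samples.
    """
    retained = table.retained
    if not retained:
        raise InsufficientDataError("no retained samples to summarize")
    summary: dict = {"n_retained": len(retained), "n_removed": len(table.removed_ids)}
    for metric, (mean_f, sd_f) in _METRIC_FIELDS.items():
        vals = np.array([getattr(s, mean_f) for s in retained])
        lo, hi = retained[int(np.argmin(vals))], retained[int(np.argmax(vals))]
        cohort_mean, cohort_sd = _mean_sd(vals)
        summary[metric] = {
            "min": {
                "sample_id": lo.sample_id,
                "mean": getattr(lo, mean_f),
                "sd": getattr(lo, sd_f),
            },
            "max": {
                "sample_id": hi.sample_id,
                "mean": getattr(hi, mean_f),
                "sd": getattr(hi, sd_f),
            },
            "cohort_mean": cohort_mean,
            "cohort_sd": cohort_sd,
        }
    return summary
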