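"""From per-frame detections to a terminal velocity per repetition.

One *repetition* is one monitored free fall of one sample.  Its vertical
positions are regressed against time by ordinary least squares; the slope
is the terminal velocity (downward-positive Y convention) and the
coefficient of determination R² is the quality gate: repetitions with
R² below 0.9999 are eliminated, and at least 10 usable frames are
required for the fit at all.

The per-repetition size statistic is the *maximum* detected radius over
the repetition's good frames — for an aspherical sample tumbling as it
falls, the maximum projection tracks the largest semi-axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .detect import FrameDetection
from .errors import (
    DegenerateTrackError,
    InsufficientDataError,
    InvalidParameterError,
    RisingSampleError,
    TooFewFramesError,
)

__all__ = [
    "RepetitionTrack",
    "RepetitionResult",
    "DEFAULT_R2_THRESHOLD",
    "DEFAULT_MIN_FRAMES",
    "fit_terminal_velocity",
    "screen_repetition",
    "repetition_radius",
    "track_from_detections",
]

DEFAULT_R2_THRESHOLD = 0.9999
DEFAULT_MIN_FRAMES = 10


@dataclass
class RepetitionTrack:
    """Times, vertical positions and (optionally) radii of one repetition."""

    sample_id: str
    repetition_index: int
    times_s: np.ndarray
    y_um: np.ndarray
    radii_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.radii_um is not None:
            self.radii_um = np.asarray(self.radii_um, dtype=float)
        if self.times_s.size == 0:
            raise InvalidParameterError("track needs at least one point")
        if self.times_s.shape != self.y_um.shape:
            raise InvalidParameterError("times and positions must have equal length")
        if self.radii_um is not None and self.radii_um.shape != self.times_s.shape:
            raise InvalidParameterError("radii must match times in length")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise InvalidParameterError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times_s)


@dataclass(frozen=True)
class RepetitionResult:
    """OLS fit of one repetition plus the screening verdict."""

    sample_id: str
    repetition_index: int
    terminal_velocity_um_s: float
    intercept_um: float
    r_squared: float
    n_frames: int
    max_radius_um: float = math.nan
    accepted: bool = False


def track_from_detections(
    detections: Sequence[FrameDetection],
    timestamps_s: Sequence[float],
    sample_id: str = "sample",
    repetition_index: int = 0,
) -> RepetitionTrack:
    """Build a track from the *ok* frames of a detection sequence.

    Frames with any non-ok status are excluded (not interpolated).
    """
    ok = [d for d in detections if d.ok]
    if not ok:
        raise InsufficientDataError("no ok detections in repetition")
    times = np.array([timestamps_s[d.frame_index] for d in ok], dtype=float)
    y = np.array([d.center_y_um for d in ok], dtype=float)
    r = np.array([d.radius_um for d in ok], dtype=float)
    return RepetitionTrack(sample_id, repetition_index, times, y, r)


def fit_terminal_velocity(
    track: RepetitionTrack,
    min_frames: int = DEFAULT_MIN_FRAMES,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
) -> RepetitionResult:
    """OLS regression of Y position on time.

    Slope = terminal velocity (µm/s, positive means falling), R² = squared
    Pearson correlation.  Raises for fewer than ``min_frames`` points,
    zero time variance, or a negative slope (a rising object is outside
    the free-fall protocol).
    """
    n = len(track)
    if n < min_frames:
        raise TooFewFramesError(
            f"{n} usable frames < minimum {min_frames} required for the fit"
        )
    t, y = track.times_s, track.y_um
    if np.ptp(t) == 0:
        raise DegenerateTrackError("zero time variance in track")
    fit = stats.linregress(t, y)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    if fit.slope < 0:
        raise RisingSampleError(
            f"negative slope {fit.slope:.3g} µm/s: sample is rising, not falling"
        )
    max_r = float(np.nanmax(track.radii_um)) if track.radii_um is not None else math.nan
    result = RepetitionResult(
        sample_id=track.sample_id,
        repetition_index=track.repetition_index,
        terminal_velocity_um_s=float(fit.slope),
        intercept_um=float(fit.intercept),
        r_squared=r2,
        n_frames=n,
        max_radius_um=max_r,
    )
    return replace(result, accepted=screen_repetition(result, r2_threshold))


def screen_repetition(
    result: RepetitionResult, r2_threshold: float = DEFAULT_R2_THRESHOLD
) -> bool:
    """R² quality gate: accept iff ``r_squared >= r2_threshold``."""
    if not 0 < r2_threshold <= 1:
        raise InvalidParameterError("r2_threshold must be in (0, 1]")
    return bool(result.r_squared >= r2_threshold)


def repetition_radius(detections: Sequence[FrameDetection]) -> float:
    """Maximum radius (µm) over the repetition's ok frames."""
    radii = [d.radius_um for d in detections if d.ok]
    if not radii:
        raise InsufficientDataError("no ok detections to take a radius from")
    return float(max(radii))
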