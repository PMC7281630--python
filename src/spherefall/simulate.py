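"""Synthetic free-fall data: ground-truth tracks, rendered frame stacks,
and whole labelled cohorts.

The generator produces exactly what the instrument produces — per-frame
positions (or brightfield frames) of a sphere-like object falling at its
Stokes terminal velocity — from known ground truth, so every stage of
the analysis pipeline can be tested against the truth that generated its
input.

Physical realism notes:

* The true velocity transient is nanoseconds long for cell-sized samples
  and cannot be seen at a 0.1 s frame interval.  To let tests exercise
  the R² screen, ``transient_time_override_s`` stretches the transient
  to an (explicitly non-physical) visible time scale.
* A rigid sphere's projected radius is constant, so the default
  per-frame radius jitter is zero; radius measurement error arises in
  the render→detect path through pixel noise.  ``radius_noise_sd_um``
  remains available for sensitivity studies.
* An aspherical sample is modelled as a spheroid with semi-axes a ≥ b
  tumbling about a horizontal axis; its projection is an ellipse whose
  vertical semi-axis oscillates between b and a, matching the
  observation that irregular samples rotate while falling.

Everything is driven by integer seeds through numpy Generators; a fixed
seed reproduces every output bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._coverage import ellipse_coverage
from .core import (
    DEFAULT_CONSTANTS,
    MediumState,
    PhysicsConstants,
    SpherePhysical,
    position_at_time,
    terminal_velocity,
    transient_time,
    weight_ng,
)
from .detect import FrameStack
from .errors import FieldOfViewError, InvalidParameterError
from .track import RepetitionTrack

__all__ = [
    "SimConfig",
    "OutlierShift",
    "SimulatedSample",
    "simulate_track",
    "render_stack",
    "simulate_cohort",
    "projected_radii",
]

#: default medium: water-like buffer at room temperature
DEFAULT_MEDIUM = MediumState(viscosity_mpa_s=1.0, density_fg_um3=1000.0)


@dataclass(frozen=True)
class SimConfig:
    """Ground truth and noise model for one simulated sample.

    Defaults describe a 90 µm polystyrene-like bead imaged every 0.1 s
    over 12 frames with mild sub-pixel tracking jitter.
    """

    true_density_fg_um3: float = 1050.0
    radius_um: float = 45.0
    #: second spheroid semi-axis; None → sphere
    semi_axis_b_um: float | None = None
    rotation_rate_rad_s: float = 0.0
    medium: MediumState = DEFAULT_MEDIUM
    constants: PhysicsConstants = DEFAULT_CONSTANTS
    v0_um_s: float = 0.0
    include_transient: bool = False
    #: non-physical stretched transient, purely for testing the R² screen
    transient_time_override_s: float | None = None
    frame_interval_s: float = 0.1
    n_frames: int = 12
    centroid_noise_sd_um: float = 0.03
    radius_noise_sd_um: float = 0.0
    pixel_noise_sd: float = 0.0
    pixel_size_um: float = 1.0
    image_shape: tuple[int, int] = (420, 128)
    background_level: float = 220.0
    foreground_level: float = 40.0
    #: starting vertical position; None → one radius below the top margin
    y0_um: float | None = None
    #: horizontal position; None → image centre
    x_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_density_fg_um3 > 0:
            raise InvalidParameterError("true density must be > 0")
        if not self.radius_um > 0:
            raise InvalidParameterError("radius must be > 0")
        if self.semi_axis_b_um is not None and not 0 < self.semi_axis_b_um <= self.radius_um:
            raise InvalidParameterError("semi_axis_b must be in (0, radius]")
        if self.n_frames < 1:
            raise InvalidParameterError("n_frames must be >= 1")
        if not self.frame_interval_s > 0:
            raise InvalidParameterError("frame_interval must be > 0")
        for name in ("centroid_noise_sd_um", "radius_noise_sd_um", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if self.transient_time_override_s is not None and not self.transient_time_override_s > 0:
            raise InvalidParameterError("transient_time_override must be > 0")
        if not self.background_level > self.foreground_level:
            raise InvalidParameterError("background must be brighter than foreground")

    # --- derived ground truth -------------------------------------------------

    @property
    def equivalent_radius_um(self) -> float:
        """Volume-equivalent sphere radius (= radius for a sphere)."""
        if self.semi_axis_b_um is None:
            return self.radius_um
        # oblate-ish spheroid with semi-axes (a, a, b)
        return (self.radius_um**2 * self.semi_axis_b_um) ** (1.0 / 3.0)

    @property
    def sphere(self) -> SpherePhysical:
        return SpherePhysical(self.equivalent_radius_um, self.true_density_fg_um3)

    @property
    def true_terminal_velocity_um_s(self) -> float:
        return terminal_velocity(self.sphere, self.medium, self.constants)

    @property
    def true_transient_time_s(self) -> float:
        if self.transient_time_override_s is not None:
            return self.transient_time_override_s
        return transient_time(self.sphere, self.medium)

    @property
    def true_weight_ng(self) -> float:
        return weight_ng(self.true_density_fg_um3, self.equivalent_radius_um)


@dataclass(frozen=True)
class OutlierShift:
    """How an injected outlier's ground truth deviates from its draw."""

    density_shift_fg_um3: float = 60.0
    radius_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.radius_factor > 0:
            raise InvalidParameterError("radius_factor must be > 0")


@dataclass
class SimulatedSample:
    """One cohort member: ground truth, label, and generated tracks."""

    sample_id: str
    config: SimConfig
    is_outlier: bool
    tracks: list[RepetitionTrack] = field(default_factory=list)

    @property
    def true_density_fg_um3(self) -> float:
        return self.config.true_density_fg_um3

    @property
    def true_radius_um(self) -> float:
        return self.config.equivalent_radius_um

    @property
    def true_terminal_velocity_um_s(self) -> float:
        return self.config.true_terminal_velocity_um_s

    @property
    def true_weight_ng(self) -> float:
        return self.config.true_weight_ng


def projected_radii(config: SimConfig, times_s: np.ndarray) -> np.ndarray:
    """Equivalent-area radius of the projected outline at each time.

    A tumbling spheroid projects an ellipse with horizontal semi-axis a
    and vertical semi-axis c(t) = sqrt(b² cos²θ + a² sin²θ), θ = ω t;
    the equivalent-area radius is sqrt(a · c).  For a sphere this is
    constantly the radius.
    """
    a = config.radius_um
    if config.semi_axis_b_um is None:
        return np.full(len(times_s), a, dtype=float)
    b = config.semi_axis_b_um
    theta = config.rotation_rate_rad_s * np.asarray(times_s, dtype=float)
    c = np.sqrt(b**2 * np.cos(theta) ** 2 + a**2 * np.sin(theta) ** 2)
    return np.sqrt(a * c)


def _rng_for(config: SimConfig, repetition_index: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, repetition_index])


def simulate_track(
    config: SimConfig,
    repetition_index: int = 0,
    sample_id: str = "sim",
) -> RepetitionTrack:
    """Ground-truth positions + seeded Gaussian noise for one repetition.

    Positions follow the analytic fall (with the exponential transient
    iff ``include_transient``) plus centroid jitter; per-frame radii are
    the true projected radii plus radius jitter.
    """
    rng = _rng_for(config, repetition_index)
    times = np.arange(config.n_frames, dtype=float) * config.frame_interval_s
    vt = config.true_terminal_velocity_um_s
    y0 = config.y0_um if config.y0_um is not None else config.radius_um + 2.0
    if config.include_transient:
        y = position_at_time(times, y0, config.v0_um_s, vt, config.true_transient_time_s)
    else:
        y = y0 + vt * times
    if config.centroid_noise_sd_um > 0:
        y = y + rng.normal(0.0, config.centroid_noise_sd_um, size=times.shape)
    radii = projected_radii(config, times)
    if config.radius_noise_sd_um > 0:
        radii = radii + rng.normal(0.0, config.radius_noise_sd_um, size=times.shape)
    return RepetitionTrack(
        sample_id=sample_id,
        repetition_index=repetition_index,
        times_s=times,
        y_um=np.asarray(y, dtype=float),
        radii_um=radii,
    )


def fitted_image_config(
    track: RepetitionTrack, config: SimConfig, margin_px: int = 8
) -> SimConfig:
    """Return a config whose image frames the whole track.

    Chooses ``image_shape`` and the horizontal position so the sample's
    outline (largest semi-axis) stays inside every frame with a margin —
    convenient when rendering samples of widely varying size and fall
    length with one base configuration.
    """
    px = config.pixel_size_um
    a_px = config.radius_um / px
    width = int(math.ceil(2 * a_px)) + 2 * margin_px
    height = int(math.ceil(float(np.max(track.y_um)) / px + a_px)) + 2 * margin_px
    return replace(config, image_shape=(height, width), x_um=(width / 2.0) * px)


def render_stack(track: RepetitionTrack, config: SimConfig) -> FrameStack:
    """Render a track as anti-aliased brightfield frames.

    Each frame is a dark disk (or tumbling-spheroid ellipse) on a bright
    background, rasterised with exact per-pixel area coverage, plus
    optional seeded additive Gaussian pixel noise.  Raises
    :class:`FieldOfViewError` naming the first frame whose outline does
    not fit inside the image.
    """
    h, w = config.image_shape
    px = config.pixel_size_um
    rng = _rng_for(config, track.repetition_index + 10_000)
    x_um = config.x_um if config.x_um is not None else (w / 2.0) * px
    frames = np.full((len(track), h, w), config.background_level, dtype=float)
    a_px = config.radius_um / px
    for i, (t, y_um) in enumerate(zip(track.times_s, track.y_um)):
        row, col = y_um / px, x_um / px
        if config.semi_axis_b_um is None:
            ar = ac = a_px
        else:
            theta = config.rotation_rate_rad_s * t
            c_um = math.sqrt(
                config.semi_axis_b_um**2 * math.cos(theta) ** 2
                + config.radius_um**2 * math.sin(theta) ** 2
            )
            ar, ac = c_um / px, a_px  # vertical semi-axis oscillates
        if row - ar < 0.5 or row + ar > h - 1.5 or col - ac < 0.5 or col + ac > w - 1.5:
            raise FieldOfViewError(
                f"frame {i}: outline (row={row:.1f}, col={col:.1f}, "
                f"semi-axes {ar:.1f}/{ac:.1f} px) leaves the {h}x{w} field of view"
            )
        cov = ellipse_coverage((h, w), row, col, ar, ac)
        frames[i] -= (config.background_level - config.foreground_level) * cov
    if config.pixel_noise_sd > 0:
        frames = frames + rng.normal(0.0, config.pixel_noise_sd, size=frames.shape)
    return FrameStack(
        frames=frames,
        timestamps_s=track.times_s.copy(),
        pixel_size_um=px,
        metadata={"sample_id": track.sample_id, "repetition_index": track.repetition_index},
    )


def _draw(dist, rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n values from a distribution spec.

    Specs: ``("uniform", lo, hi)``, ``("normal", mean, sd)``,
    ``("constant", value)`` or a callable ``f(rng, n) -> array``.
    """
    if callable(dist):
        return np.asarray(dist(rng, n), dtype=float)
    kind = dist[0]
    if kind == "uniform":
        return rng.uniform(dist[1], dist[2], size=n)
    if kind == "normal":
        return rng.normal(dist[1], dist[2], size=n)
    if kind == "constant":
        return np.full(n, float(dist[1]))
    raise InvalidParameterError(f"unknown distribution spec {dist!r}")


#: default ranges: spheroid densities and diameters observed in validation runs
DEFAULT_DENSITY_DISTRIBUTION = ("uniform", 1024.0, 1046.0)
DEFAULT_DIAMETER_DISTRIBUTION = ("uniform", 95.0, 195.0)


def simulate_cohort(
    n_samples: int,
    density_distribution=DEFAULT_DENSITY_DISTRIBUTION,
    size_distribution=DEFAULT_DIAMETER_DISTRIBUTION,
    n_repetitions: int = 9,
    outlier_fraction: float = 0.0,
    outlier_shift: OutlierShift | None = None,
    seed: int = 0,
    base_config: SimConfig = SimConfig(),
) -> list[SimulatedSample]:
    """Generate a labelled cohort of simulated samples with tracks.

    Each sample draws a true density and diameter, gets ``n_repetitions``
    independent tracks, and a fraction of samples has its ground truth
    perturbed by ``outlier_shift`` (density shifted, radius scaled) so
    that screening tests know exactly which samples should fall.
    """
    if n_samples < 1:
        raise InvalidParameterError("n_samples must be >= 1")
    if not 0 <= outlier_fraction <= 1:
        raise InvalidParameterError("outlier_fraction must be in [0, 1]")
    shift = outlier_shift or OutlierShift()
    rng = np.random.default_rng([seed, 777])
    densities = _draw(density_distribution, rng, n_samples)
    diameters = _draw(size_distribution, rng, n_samples)
    n_out = int(round(outlier_fraction * n_samples))
    outlier_idx = set(rng.choice(n_samples, size=n_out, replace=False).tolist())

    samples: list[SimulatedSample] = []
    width = len(str(n_samples))
    for i in range(n_samples):
        rho, radius = float(densities[i]), float(diameters[i]) / 2.0
        is_outlier = i in outlier_idx
        if is_outlier:
            rho += shift.density_shift_fg_um3
            radius *= shift.radius_factor
            if rho <= 0:
                raise InvalidParameterError(
                    f"outlier shift drives density non-positive ({rho:.3g})"
                )
        cfg = replace(
            base_config,
            true_density_fg_um3=rho,
            radius_um=radius,
            seed=int(np.random.default_rng([seed, i + 1]).integers(0, 2**31 - 1)),
        )
        sid = f"S{i:0{width}d}"
        tracks = [simulate_track(cfg, rep, sample_id=sid) for rep in range(n_repetitions)]
        samples.append(SimulatedSample(sample_id=sid, config=cfg, is_outlier=is_outlier, tracks=tracks))
    return samples
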