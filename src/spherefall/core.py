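"""Closed-form Stokes sedimentation physics.

A small rigid sphere of radius ``r`` and mass density ``rho_s`` falling in
a quiescent Newtonian fluid (density ``rho_l``, viscosity ``eta``) obeys

    m_s a = (rho_s - rho_l) V_s g - k v,        k = 6 pi eta r,

whose solution is an exponential relaxation

    v(t) = v_T + (v_0 - v_T) exp(-t / tau)

towards the terminal velocity, with

    v_T  = (2/9) (g / eta) (rho_s - rho_l) r**2
    tau  = m_s / k = (2/9) (rho_s / eta) r**2.

Inverting v_T gives the densitometric relation the method rests on:

    rho_s = (9/2) eta v_T / (g r**2) + rho_l

and the weight follows as ``W_s = rho_s V_s``.

For micrometre-scale biological samples in water-like media ``tau`` is
tens of nanoseconds — utterly invisible at a 0.1 s frame interval — so
the observed fall is uniform linear motion and the terminal velocity can
be read off a straight-line fit of position against time.

All functions accept scalars or numpy arrays for the kinematic arguments
and work in the µm–fg–s system of :mod:`spherefall.units`; viscosity is
taken in mPa·s and gravity in m/s² at the boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .units import (
    FG_PER_NG,
    M_S2_TO_UM_S2,
    MPAS_TO_INTERNAL,
    STANDARD_GRAVITY_M_S2,
    sphere_volume_um3,
)

__all__ = [
    "MediumState",
    "PhysicsConstants",
    "SpherePhysical",
    "MotionState",
    "BuoyantSampleWarning",
    "terminal_velocity",
    "transient_time",
    "density_from_terminal_velocity",
    "weight_ng",
    "velocity_at_time",
    "position_at_time",
    "friction_coefficient",
]


class BuoyantSampleWarning(UserWarning):
    """The sample is lighter than the medium and will rise, not sink.

    The math remains valid (negative terminal velocity) but the fall
    protocol cannot observe such a sample.
    """


@dataclass(frozen=True)
class MediumState:
    """Fluid properties of the analysis medium.

    Parameters
    ----------
    viscosity_mpa_s:
        Dynamic viscosity ``eta`` in mPa·s.
    density_fg_um3:
        Mass density ``rho_l`` in fg/µm³ (numerically kg/m³).
    temperature_c:
        Optional metadata; both ``eta`` and ``rho_l`` depend on it, but it
        never enters the computation directly.
    """

    viscosity_mpa_s: float
    density_fg_um3: float
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        if not self.viscosity_mpa_s > 0:
            raise InvalidParameterError(f"viscosity must be > 0, got {self.viscosity_mpa_s}")
        if not self.density_fg_um3 > 0:
            raise InvalidParameterError(f"medium density must be > 0, got {self.density_fg_um3}")

    @property
    def viscosity_internal(self) -> float:
        """Viscosity in fg/(µm·s)."""
        return self.viscosity_mpa_s * MPAS_TO_INTERNAL


@dataclass(frozen=True)
class PhysicsConstants:
    """Physical constants of the run; only gravity is tunable."""

    g_m_s2: float = STANDARD_GRAVITY_M_S2

    def __post_init__(self) -> None:
        if not self.g_m_s2 > 0:
            raise InvalidParameterError(f"g must be > 0, got {self.g_m_s2}")

    @property
    def g_um_s2(self) -> float:
        return self.g_m_s2 * M_S2_TO_UM_S2


DEFAULT_CONSTANTS = PhysicsConstants()


@dataclass(frozen=True)
class SpherePhysical:
    """A sphere-like sample with known radius and mass density."""

    radius_um: float
    mass_density_fg_um3: float

    def __post_init__(self) -> None:
        if not self.radius_um > 0:
            raise InvalidParameterError(f"radius must be > 0, got {self.radius_um}")
        if not self.mass_density_fg_um3 > 0:
            raise InvalidParameterError(
                f"mass density must be > 0, got {self.mass_density_fg_um3}"
            )

    @property
    def volume_um3(self) -> float:
        return sphere_volume_um3(self.radius_um)

    @property
    def mass_fg(self) -> float:
        return self.mass_density_fg_um3 * self.volume_um3

    @property
    def weight_ng(self) -> float:
        return self.mass_fg / FG_PER_NG


@dataclass(frozen=True)
class MotionState:
    """Kinematic snapshot of a falling sample (mostly for reporting)."""

    time_s: float
    velocity_um_s: float
    initial_velocity_um_s: float
    terminal_velocity_um_s: float
    transient_time_s: float
    friction_coefficient_fg_s: float
    acceleration_um_s2: float = field(default=0.0)


def _check_medium_radius(radius_um: float, medium: MediumState) -> None:
    if not radius_um > 0:
        raise InvalidParameterError(f"radius must be > 0, got {radius_um}")
    if not medium.viscosity_mpa_s > 0:  # MediumState already enforces this
        raise InvalidParameterError("viscosity must be > 0")


def friction_coefficient(radius_um: float, medium: MediumState) -> float:
    """Stokes friction coefficient ``k = 6 pi eta r`` in fg/s."""
    _check_medium_radius(radius_um, medium)
    return 6.0 * math.pi * medium.viscosity_internal * radius_um


def terminal_velocity(
    sample: SpherePhysical,
    medium: MediumState,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Terminal velocity ``v_T = (2/9)(g/eta)(rho_s - rho_l) r²`` in µm/s.

    Positive for a sinking sample (``rho_s > rho_l``); a buoyant sample
    yields a negative value and a :class:`BuoyantSampleWarning`.
    """
    _check_medium_radius(sample.radius_um, medium)
    vt = (
        (2.0 / 9.0)
        * (constants.g_um_s2 / medium.viscosity_internal)
        * (sample.mass_density_fg_um3 - medium.density_fg_um3)
        * sample.radius_um**2
    )
    if vt < 0:
        warnings.warn(
            "sample is buoyant (rho_s < rho_l): terminal velocity is negative",
            BuoyantSampleWarning,
            stacklevel=2,
        )
    return vt


def transient_time(sample: SpherePhysical, medium: MediumState) -> float:
    """Relaxation time ``tau = (2/9)(rho_s/eta) r²`` in seconds.

    This is the time constant of the exponential approach to terminal
    velocity; for cell-sized samples in water it is of order 10–100 ns.
    """
    _check_medium_radius(sample.radius_um, medium)
    return (
        (2.0 / 9.0)
        * (sample.mass_density_fg_um3 / medium.viscosity_internal)
        * sample.radius_um**2
    )


def density_from_terminal_velocity(
    vt_um_s: float,
    radius_um: float,
    medium: MediumState,
    constants: PhysicsConstants = DEFAULT_CONSTANTS,
) -> float:
    """Invert Stokes' law: ``rho_s = (9/2) eta v_T / (g r²) + rho_l``.

    Exact inverse of :func:`terminal_velocity` for the same medium,
    constants and radius.
    """
    _check_medium_radius(radius_um, medium)
    return (
        4.5 * medium.viscosity_internal * vt_um_s / (constants.g_um_s2 * radius_um**2)
        + medium.density_fg_um3
    )


def weight_ng(mass_density_fg_um3: float, radius_um: float) -> float:
    """Sample weight ``W_s = rho_s V_s`` in nanograms."""
    if radius_um < 0:
        raise InvalidParameterError(f"radius must be >= 0, got {radius_um}")
    return mass_density_fg_um3 * sphere_volume_um3(radius_um) / FG_PER_NG


def velocity_at_time(t_s, v0_um_s: float, vt_um_s: float, tau_s: float):
    """Velocity of the relaxing fall, ``v(t) = v_T + (v_0 - v_T) e^{-t/tau}``."""
    if not tau_s > 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau_s}")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    out = vt_um_s + (v0_um_s - vt_um_s) * np.exp(-t / tau_s)
    return out if out.ndim else float(out)


def position_at_time(t_s, y0_um: float, v0_um_s: float, vt_um_s: float, tau_s: float):
    """Analytic integral of the velocity law.

    ``y(t) = y0 + v_T t + (v_0 - v_T) tau (1 - e^{-t/tau})``; as
    ``t >> tau`` this approaches the straight line the regression fits.
    """
    if not tau_s > 0:
        raise InvalidParameterError(f"tau must be > 0, got {tau_s}")
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("time must be >= 0")
    out = y0_um + vt_um_s * t + (v0_um_s - vt_um_s) * tau_s * (1.0 - np.exp(-t / tau_s))
    return out if out.ndim else float(out)
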