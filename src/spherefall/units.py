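"""Unit system and conversions.

All internal computation uses a µm–fg–s system chosen so that every
quantity the method reports is already in its natural output unit:

====================  ==================  =============================
quantity              internal unit       notes
====================  ==================  =============================
length                µm
time                  s
mass                  fg
mass density          fg/µm³              numerically equal to kg/m³
velocity              µm/s
viscosity             fg/(µm·s)           1 mPa·s = 1e9 fg/(µm·s)
gravity               µm/s²               9.80665 m/s² = 9.80665e6
weight (reported)     ng                  1 ng = 1e6 fg
====================  ==================  =============================

Conversions happen only at the API boundary: users supply viscosity in
mPa·s and gravity in m/s², results come back in µm/s, fg/µm³ and ng.
"""

import math

#: multiply a viscosity in mPa·s by this to get fg/(µm·s)
MPAS_TO_INTERNAL = 1.0e9

#: standard gravity, m/s²
STANDARD_GRAVITY_M_S2 = 9.80665

#: multiply an acceleration in m/s² by this to get µm/s²
M_S2_TO_UM_S2 = 1.0e6

#: femtograms per nanogram
FG_PER_NG = 1.0e6


def sphere_volume_um3(radius_um: float) -> float:
    """Volume of a sphere, µm³."""
    return (4.0 / 3.0) * math.pi * radius_um**3


def water_viscosity_mpa_s(temperature_c: float) -> float:
    """Dynamic viscosity of pure water in mPa·s.

    Empirical correlation (valid ~0–100 °C, better than 1% around room
    temperature)::

        log10(eta/eta20) = ((20-T)*1.3272 - 0.001053*(20-T)**2) / (T + 105)

    with ``eta20 = 1.0020`` mPa·s.  Offered as an optional helper for
    water-like media; the analysis itself never substitutes it silently —
    viscosity is always an explicit user input.
    """
    if not -10.0 < temperature_c < 150.0:
        raise ValueError(f"temperature {temperature_c} °C outside supported range")
    dt = 20.0 - temperature_c
    return 1.0020 * 10.0 ** ((dt * 1.3272 - 0.001053 * dt * dt) / (temperature_c + 105.0))
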