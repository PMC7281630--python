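"""Closed-form sedimentation physics: from density to velocity and back.

A 50 µm polystyrene-like bead (1050 fg/µm³) falling in a water-like
medium: terminal velocity, relaxation time, and the inverse problem the
densitometry method solves — recovering the density from the velocity.
"""

import spherefall as sf

medium = sf.MediumState(viscosity_mpa_s=1.0, density_fg_um3=1000.0)
bead = sf.SpherePhysical(radius_um=25.0, mass_density_fg_um3=1050.0)

vt = sf.terminal_velocity(bead, medium)
tau = sf.transient_time(bead, medium)
print(f"terminal velocity : {vt:8.2f} µm/s")
print(f"transient time    : {tau*1e6:8.3f} µs  (invisible at 0.1 s frames)")

rho = sf.density_from_terminal_velocity(vt, bead.radius_um, medium)
print(f"inverted density  : {rho:8.2f} fg/µm³  (exact round trip)")
print(f"weight            : {sf.weight_ng(rho, bead.radius_um):8.2f} ng")

# the reference worked example: a 1 µm cell-like particle relaxes in ~60 ns
cell = sf.SpherePhysical(radius_um=0.5, mass_density_fg_um3=1020.0)
print(f"1 µm sample tau   : {sf.transient_time(cell, medium)*1e9:8.1f} ns")
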