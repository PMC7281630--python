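# spherefall

Stokes sedimentation velocimetry for sphere-like biological samples:
**mass density, size and weight** of microbeads and live 3D tumor
spheroids (tens to hundreds of micrometres), measured from the terminal
velocity of their free fall in a quiescent medium.

## Who it is for

Labs that monitor 3D cell cultures (spheroids, organoids) or calibrate
flow instruments with polystyrene beads, and need the quantity imaging
alone cannot give: the sample's mass density, and with it the weight.
The package covers the full chain from brightfield frame stacks (or
pre-extracted position tracks) to screened, cohort-level statistics —
plus a physics-faithful simulator, so the whole pipeline runs and is
testable with no instrument attached.

## The method

A small rigid sphere (radius $r$, density $\rho_s$) falling in a fluid of
density $\rho_l$ and viscosity $\eta$ relaxes exponentially, with time
constant $\tau = \tfrac{2}{9}\,\rho_s r^2/\eta$, to the terminal velocity

$$v_T = \frac{2}{9}\frac{g}{\eta}(\rho_s-\rho_l)\,r^2 .$$

For micrometre-scale samples in water-like media $\tau$ is tens of
nanoseconds — invisible at a 0.1 s frame interval — so the observed fall
is uniform motion and $v_T$ is the slope of a straight-line fit of
vertical position against time. Inverting Stokes' law gives the
densitometric relation

$$\rho_s = \frac{9}{2}\frac{\eta\, v_T}{g\, r^2} + \rho_l ,
\qquad W_s = \rho_s \cdot \tfrac{4}{3}\pi r^3 .$$

The measurement protocol around the physics:

1. **Detection** — each frame is Otsu-thresholded (dark object, bright
   background); the largest blob gets a *circular reference*: sub-pixel
   intensity-weighted centroid and equivalent-area radius $\sqrt{A/\pi}$.
2. **Regression screen** — per repetition, $v_T$ by OLS over ≥ 10 frames;
   repetitions with $R^2 < 0.9999$ are eliminated (they indicate
   asphericity, rotation or disturbed flow).
3. **Aggregation gate** — a sample's *final radius* is the mean of the
   per-repetition maximum radii; densities and weights are computed per
   accepted repetition; samples with fewer than 5 accepted repetitions
   (of the canonical 9) are discarded.
4. **Cohort screen** — Shapiro–Wilk normality per output metric
   (terminal velocity, density, diameter, weight); Tukey box-plot fences
   ($k=1.5$) on non-normal metrics; a sample flagged in **any** metric is
   removed, then normality is re-tested once.

Everything works in a µm–fg–s unit system (1 fg/µm³ = 1 kg/m³
numerically), so densities read like kg/m³ and weights come out in ng.

## Worked example

`examples/05_bead_validation.py` simulates the bead calibration design —
7 beads × 7 repetitions for each of the 20, 50 and 90 µm sizes at the
declared 1050 fg/µm³ — and runs the full pipeline:

```
 20 µm beads: density  1049.987 ± 0.053 fg/µm³
 50 µm beads: density  1049.999 ± 0.009 fg/µm³
 90 µm beads: density  1050.000 ± 0.002 fg/µm³

grand mean over 21 beads: 1049.995 fg/µm³ (declared 1050 ± 10)
all per-bead values span 0.161 fg/µm³
```

Each line is the mean ± SD of per-bead densities for one size; the
per-bead spread (0.16 fg/µm³) is far inside the supplier's ±10
declaration, and shrinks with bead size because the regression resolves
faster falls better. The other examples cover the closed-form physics
(`01`), the R² screen (`02`), rendering + sub-pixel detection (`03`) and
the 87-sample cohort screening benchmark (`04`).

## Library and CLI

```python
import spherefall as sf

medium = sf.MediumState(viscosity_mpa_s=1.0, density_fg_um3=1000.0)
track  = sf.read_tracks_csv("tracks.csv")[0]        # or detect a TIFF stack
fit    = sf.fit_terminal_velocity(track)            # slope, R², screen
rho    = sf.density_from_terminal_velocity(fit.terminal_velocity_um_s,
                                           fit.max_radius_um, medium)
```

A thin CLI mirrors the protocol stages — `spherefall simulate | calibrate |
detect | track | analyze | pipeline` — each stage consuming the previous
stage's CSV, so imaging-free use from track CSVs is first-class:

```sh
spherefall simulate --n-samples 5 --seed 1 --out sim/
spherefall analyze sim/tracks.csv --out results/
```

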