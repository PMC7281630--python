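# Methods

This note documents the model, the protocol constants, the synthetic
data generator, and the numerical/design choices behind `spherefall`.

## Physical model

The sample is treated as a rigid sphere at low Reynolds number in an
unbounded quiescent Newtonian fluid. Its equation of motion balances
net gravity against Stokes drag,

    m_s a = (rho_s - rho_l) V_s g - k v,    k = 6 pi eta r,

giving an exponential relaxation `v(t) = v_T + (v_0 - v_T) e^{-t/tau}`
with `v_T = (2/9)(g/eta)(rho_s - rho_l) r²` and
`tau = (2/9)(rho_s/eta) r²`. The analysis inverts `v_T` for `rho_s` and
derives the weight `W = rho_s (4/3) pi r³`.

Assumptions, and what is deliberately out of scope:

* **Stokes regime.** For the supported size range (20–200 µm diameter)
  and density contrasts (tens of fg/µm³), Reynolds numbers stay ≪ 1.
  Finite-Re drag corrections and wall effects of a mm-scale channel are
  not modelled.
* **Sphericity.** Aspherical samples violate the drag law; the protocol
  handles them statistically (R² screen, max-radius rule, outlier
  removal) rather than with non-spherical drag laws.
* **Quiescent medium.** Residual flow shows up as a biased slope; a
  *rising* sample raises a dedicated error instead of returning a
  negative velocity from the fit. Buoyant samples are supported by the
  closed forms (negative `v_T`, with a warning) but not by the fall
  protocol.
* **Transient.** `tau` is 10–100 ns for the supported samples, so the
  observed motion is uniform; the transient matters only as the thing
  the R² screen would catch if it were visible.

## Units

Internal unit system µm–fg–s: 1 fg/µm³ = 1 kg/m³ numerically,
1 mPa·s = 1e9 fg/(µm·s), g = 9.80665e6 µm/s² by default (overridable).
Conversions happen once, at the API boundary; every tabular column name
carries its unit (`vT_um_s`, `density_fg_um3`, …).

Viscosity and medium density are always explicit user inputs. A helper
for water viscosity vs. temperature exists (`units.water_viscosity_mpa_s`)
but is never substituted silently: buffer properties at the operating
temperature are the user's responsibility.

## Protocol constants (defaults, all configurable via `RunConfig`)

| constant | default | meaning |
|---|---|---|
| `frame_interval_s` | 0.1 | acquisition interval |
| `min_frames` | 10 | minimum usable frames per regression |
| `r2_threshold` | 0.9999 | repetition acceptance on R² |
| `repetitions_per_sample` | 9 | canonical repetition count |
| `min_accepted_repetitions` | 5 | per-sample validity gate |
| `tukey_k` | 1.5 | box-plot fence multiplier |
| `alpha` | 0.05 | Shapiro–Wilk significance for the normality verdict |

Quartiles use linear interpolation of order statistics (numpy's default
`linear` method). This is documented because fence membership near the
boundary can differ between quartile conventions; the tests pin the
convention with a brute-force oracle.

## Detection design

* **Threshold**: global Otsu with dark-object polarity — parameter-free
  and auditable (the threshold is recorded per frame).
* **Circle assignment**: largest connected component; centre = area
  centroid, radius = equivalent-area radius `sqrt(A/pi)`. Both are
  refined with grayscale weighting: near the boundary a pixel's darkness
  is proportional to the covered fraction of the pixel, so the
  normalised darkness summed over the blob neighbourhood estimates the
  area with sub-pixel precision (exactly, on clean two-level images).
  Background/foreground reference levels are medians taken far from and
  deep inside the blob, which keeps the refinement robust to moderate
  pixel noise.
* **Isolation**: a second component above 20% of the largest flags
  `multiple-objects` (the software analogue of the operator checking
  that no other sample is nearby). Components touching the image border
  are flagged `border`, because a clipped blob would bias the
  maximum-radius rule.
* Non-ok frames are excluded from the track, never interpolated; the
  ≥ 10-frame requirement applies after exclusion.

## Aggregation

The per-repetition radius statistic is the **maximum** over good frames
(a tumbling aspherical sample's maximum projection tracks its largest
semi-axis); the sample's *final radius* is the mean of those maxima over
accepted repetitions. Density is computed per accepted repetition from
that repetition's `v_T` and the **sample-level** final radius — there is
one final radius per sample; `radius_mode="repetition"` switches to
per-repetition radii for sensitivity analysis. Spreads are sample
standard deviations (ddof = 1); identical inputs yield exactly zero SD.

## Cohort screen

Single pass: Shapiro–Wilk per metric; Tukey fences on metrics with a
non-normal verdict (configurable to all metrics); any-category removal;
one normality re-test on the retained set. No iteration — re-screening
the survivors would change the test's meaning and is not part of the
protocol.

A practical caveat the simulator makes visible: terminal velocity is a
product of density contrast and radius squared, so over a wide size
range its distribution is right-skewed even for a perfectly clean
cohort, and Tukey fences on a skewed metric can occasionally flag
extreme-but-clean samples. With genuinely contaminated cohorts the
outliers widen the fences and recovery of the injected labels is exact;
on clean cohorts the screen is conservative rather than neutral. This
is a property of box-plot screening itself, not of the implementation.

## Synthetic data generator

What it emulates: per-frame positions of a uniformly falling sample
(0.1 s intervals, 12 frames by default), sub-pixel tracking jitter
(Gaussian, σ = 0.03 µm by default), rendered brightfield frames (dark
object ~40 on bright ~220, exact area-coverage anti-aliasing, optional
additive Gaussian pixel noise), tumbling spheroids (projected ellipse
with oscillating vertical semi-axis), and whole labelled cohorts.

Deliberate design choices:

* **Rendering is exact.** Pixel values use the closed-form area of the
  disk/ellipse–pixel intersection, not supersampling, so the rendered
  "ink" equals the true projected area to machine precision and the
  noiseless render→detect→fit loop closes with density bias ~1e-5
  fg/µm³. Sub-pixel motion moves intensity smoothly between boundary
  pixels, as on a real detector.
* **Default radius jitter is zero.** A rigid sphere's projection is
  constant; radius measurement error belongs to the render→detect path
  (pixel noise) and remains available as an explicit knob
  (`radius_noise_sd_um`). This also keeps the max-radius rule unbiased
  in track-mode simulations, which the bead-validation design
  implicitly assumes.
* **Transient override.** Real transients are nanoseconds; the
  simulator's `transient_time_override_s` stretches them to visible
  time scales *purely* so the R² screen has something to reject. It is
  labelled non-physical.
* **Cohort distributions.** Densities are drawn uniformly in
  [1024, 1046] fg/µm³ and diameters uniformly in [95, 195] µm — the
  observed spheroid ranges of the validation study. Bounded draws also
  give the screening benchmark a clean ground truth: a bounded metric
  cannot exceed its own Tukey fences, so injected outliers (default:
  density shifted by +60 fg/µm³) are exactly the samples the screen
  should remove. The 87-samples / 15-outliers benchmark recovers the
  labels exactly across seeds.
* **Seeding.** Every randomness source derives from integer seeds via
  `numpy.random.default_rng([seed, stream])`; a fixed seed reproduces
  tracks, frames and cohorts bit-for-bit.

What the generator does **not** model — and hence what passing tests do
not show about real data: optical physics (diffraction, defocus,
illumination gradients), deformation or internal structure of
spheroids, flow disturbances, temperature drift, or non-Gaussian camera
noise. Real-instrument noise magnitudes are not published; the defaults
are plausible stand-ins chosen so that default cohorts pass the R²
screen at roughly the rates the protocol reports (most repetitions
accepted, slowest/smallest samples occasionally rejected).

## Problem sizes

The test suite and examples run the complete designs at their natural
sizes — 21 beads × 7 repetitions, 87 spheroids × 9 repetitions — since
track-level simulation is cheap; rendering-based tests use single
repetitions of a 90 µm bead at 1 µm/px (420×128 px frames), which is
where the sub-pixel claims are sharpest.

## Known limitations

* Calibration assumes a single high-contrast bar/gap; it measures the
  bounding-box extent of the largest dark component, which is correct
  for the intended reference target but not for arbitrary scenes.
* The detector handles one sample per frame by design; multi-sample
  tracking is out of scope.
* R² is reported from simple OLS; no robust or weighted variants.
* The screen's behaviour on heavily skewed clean metrics (above) means
  cohort composition should be kept in mind when interpreting removal
  counts.
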