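# Methods

This note records the model behind `corrdop`, the choices made where the
design was genuinely open, and what the synthetic validation does and
does not demonstrate.

## Estimation model

Flow is estimated from the frame-to-frame motion of the RF speckle
pattern along each A-line.  For adjacent lines *i* and *i+1*, a window of
25 interpolated samples around each centre is compared at integer lags
within ±15 interpolated samples using the normalized zero-mean
cross-correlation (Pearson correlation of the two windows).  The lag
maximising the correlation, `P_shift`, measures the axial displacement
per PRF interval; ties resolve to the smaller |lag| and then the
non-negative lag.  Sign convention: an echo arriving *earlier* in the
later line means motion toward the transducer and positive velocity
(rendered red/orange; receding flow is blue/cyan).

Velocity resolution is `V_res = (c/2) f_prf / (f_s n_res)`; with the
default acquisition (1540 m/s, 1 kHz, 180 MHz, ×3 interpolation) one lag
step is 1.4259 mm/s.  Optional parabolic refinement fits a parabola
through the correlation peak and its two neighbours and refines the lag
to a real value clamped to ±0.5 of the peak; for a carrier near 15 MHz
sampled at 540 MHz after interpolation the autocorrelation is locally
cosine-like and the parabolic estimate is nearly unbiased, which is why
the validation experiments enable it: at the lowest phantom speed the
true shift is only 0.22 interpolated samples and integer quantisation
alone would dominate the error.  Integer mode remains the default
because the shift is then an exact argmax, reproducible against a
brute-force oracle.

### Noise rejection

Band-limited noise correlates strongly over a 25-sample window (only a
handful of independent samples at a 27 MHz bandwidth), so two gates
precede any velocity conversion:

* **Amplitude mask** — the envelope (magnitude of the analytic signal
  per A-line) must exceed `noise_factor × floor` over the whole window on
  both lines, where `floor` is the mean absolute amplitude of a
  signal-free region (the pre-surface samples; first 200 samples as the
  fallback).  The floor is measured **before** surface alignment: the
  zero fill that alignment introduces at line ends would bias it low, an
  effect that in testing let pure-noise windows through and shrank
  velocity estimates by tens of percent.  A relative lower bound of
  10⁻³ of the peak amplitude keeps the threshold meaningful for
  noiseless synthetic input, where the measured "floor" is only filter
  ringing.
* **Correlation gate** — windows with peak correlation below `rho_min`
  (default 0.7; the threshold is deliberately configurable since only
  the *use* of correlation-amplitude filtering, not a value, is fixed by
  the method) are dropped.

On noise-only input the two gates together leave well under 1% of
windows valid, verified over multiple seeds.

### Preprocessing

* FIR band-pass 3–30 MHz, 301-tap Kaiser design (β = 4.55), applied with
  `mode='same'` convolution so the odd-length linear-phase filter is
  group-delay compensated.  The tap count is sized for ≥ 40 dB rejection
  at half the low band edge (1.5 MHz) — a ~1.5 MHz transition at 180 MHz
  sampling; measured attenuation is 54 dB there and 73 dB at 45 MHz with
  0.03 dB in-band ripple.
* Axial interpolation is Fourier-domain resampling (band-limited), which
  preserves the original samples at stride `n_res` and, unlike linear
  interpolation, does not bias sub-sample shift estimates.

### Surface referencing (rotational scans)

The US channel's water–tissue interface provides the registration
reference.  Arrival detection thresholds a **trailing moving average**
(one pulse length, 31 samples) of the envelope at 10 dB above the noise
floor: raw-envelope first-crossing false-triggers in the noise region
with near certainty (the per-sample Rayleigh exceedance at the 10 dB
threshold is ≈ 4%), while the causal window both suppresses isolated
noise peaks and guarantees detection never precedes the echo onset.  The
first `smooth−1` samples of a line are not eligible (a truncated window
is just the raw envelope again).  Detection carries a constant offset of
a few samples — harmless, since alignment and angle estimation depend
only on relative arrivals.

Outlier rejection replaces points deviating from a 15-line sliding
median (circular for full revolutions) by more than 5× the median
absolute deviation; the threshold never drops below 3 samples so that
detection quantisation on a smooth surface is not "rejected".  PA lines
are then shifted by integer samples to a common median arrival, and
window centres are shifted back afterwards for co-registration.

### Angle compensation

θ is the unsigned angle between the A-line direction and the local
surface tangent, with flow assumed parallel to the surface.  The default
"exact" mode solves the chord triangle between adjacent surface points
(r_{i−1} at azimuth 0, r_i at `dphi`) in closed form; it satisfies the
unapproximated law-of-sines identity to 10⁻⁹ and needs no initial
condition.  The small-angle law-of-sines recursion is available as
`mode="recursive"`, implemented in the numerically stable orientation
`sin θ_i = r_{i−1} sin(dphi + θ_{i−1}) / r_i` (the transposed orientation
compounds a growth factor and saturates at 90° within tens of lines),
seeded with the exact angle of the first line.  All angles are capped at
70° before compensation; `1/cos θ` then stays within [1, 2.9238].

## The simulator

The generator is kinematic, not acoustic: ideal point absorbers are
convolved with a Gaussian-enveloped cosine pulse (15 MHz centre, 115%
−6 dB fractional bandwidth, truncated at −60 dB) placed at exact
fractional-sample arrival times under the same propagation convention as
the estimator (round-trip, `c/2`, by default).  Scatterers live on a 1-D
pattern along the beam chord through the flow structure (80 per mm,
several per resolution cell, standard-normal amplitudes) and advect by
`v cos θ / f_prf` per interval with periodic wrap-around, so adjacent
lines are locally shifted copies.  Plug flow is the default; a parabolic
profile scales each scatterer's speed by its initial transverse position.
White Gaussian noise is added at a prescribed SNR relative to the RMS RF
inside the flow region, and the realized signal/noise RMS are recorded in
the scan metadata.  The US channel carries strong static wall/surface
echoes (~40 dB above the noise) plus the same noise level.

Geometries:

* **Linear tube** — 580 µm bore crossed at a configurable angle
  (default 60°), stationary beam.
* **Spiral** — the tube wraps a cylinder; with pitch angle
  α = atan(pitch / 2πR) and probe tilt τ the beam meets the helix tangent
  at the constant angle `cos θ = sin τ · sin α` (the tangent has no
  radial component, so θ is azimuth-independent — the geometric reason a
  single constant-angle correction applies).  Defaults (pitch = 2πR,
  τ = 45°) give θ = 60°.  A slow sinusoidal surface wobble (17 µm over a
  revolution) emulates tissue displacement and exercises the alignment.
* **Lumen** — per-line surface radius from a caller-supplied function,
  with a 0.5 mm superficial flow layer whose per-line axial velocity
  follows the analytic surface-tangent angle.

Deliberate idealizations, and hence what passing tests do *not* show
about real data: the beam is a line (no lateral beam width, diffraction,
or focusing), so the simulator neglects migration of the beam footprint
along the tube between rotational lines — physically this is excused by
the finite lateral resolution of a focused transducer, but it means
speckle decorrelation from lateral motion is absent; there is no acoustic
attenuation, fluence variation with depth, or frequency-dependent
scattering; noise is white and stationary; and the periodic scatterer
wrap creates a recirculation seam at which windows legitimately
decorrelate (tests of per-window exactness therefore exclude a margin
near the bore walls).

## Validation experiments and problem sizes

The in-silico twins of the phantom experiments run with sub-sample
refinement on and fixed seeds `{seed, seed+1, seed+2}`:

* **Linearity** — ten speeds 0.63–6.3 mm/s, 60°, SNR 20 dB, 201 lines
  per scan, three seeds per speed; per-speed mean estimate vs truth is
  fitted by ordinary least squares.  201 lines keeps a single sweep
  under a minute while leaving ~7000 valid windows per scan.
* **Angle sweep** — 70/60/50° at 6.3 mm/s; reports uncompensated
  (≈ v cos θ) and compensated (≈ v) means, with the 70° cap applied
  above it.
* **Spiral** — six speeds 1–6 mm/s, full 1000-line revolutions, surface
  detection → outlier rejection → alignment → correlation →
  constant-angle compensation at the analytically known 60° →
  100-pair ROI averaging; per-speed estimate is the mean unsigned block
  velocity.

Estimates average *signed* velocities before taking the magnitude, so
sub-sample refinement scattering low-speed windows around zero does not
bias speeds upward; ROI blocks are declared valid when at least 10% of
their members survive gating.

## Numerical details and edge cases

* Correlation windows are only evaluated where the full lag excursion
  stays in bounds; windows with (near-)zero variance are invalid.
* Parabolic refinement is skipped at the lag-search boundary and when
  the three-point stencil is not concave.
* `roi_average` keeps a trailing partial block only if at least half a
  block long.
* Degenerate pooled t-test inputs: zero variance with equal means gives
  (t=0, p=1); zero variance with unequal means returns p=0 with a
  warning.
* The polar warp uses bilinear sampling on a square raster spanning the
  outer radius; pixels off the sampled annulus, or touched by NaN input
  (masked velocity), are NaN.
* HDF5 containers are versioned (`layout_version` attribute); arrays are
  float64 and round-trip bit-exactly.

## Known limitations

Beyond the simulator idealizations above: only adjacent-line pairs are
correlated (no multi-lag ensemble averaging); flow direction is assumed
parallel to the detected surface, so individual vessels at other
orientations are mis-compensated (per-vessel tracking is out of scope);
alignment shifts are integer original samples, leaving sub-sample
registration jitter that widens — but does not bias — the estimate
distribution on steeply sloped surfaces; and processing is offline batch,
with no real-time path.
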