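# Methods

`fpmscope` implements the complete computational chain of an LED-array
Fourier ptychographic microscope (FPM) at desk scale: synthetic ground-truth
objects, a coherent forward model of the acquisition, iterative
reconstruction with embedded pupil recovery, and resolving-power evaluation
from USAF 1951 bar targets.  This note records the model, its assumptions,
the numerical choices, and what the simulations do and do not show about a
physical instrument.

## Optical model and conventions

A thin sample is described by its complex transmission
`s(x) = A(x) exp(i φ(x))` on a square grid with pixel size `Δx` (µm).
An LED at lateral offset `(x, y)` and stage distance `z` illuminates the
sample with a tilted plane wave of transverse wave vector
`k_m = (2π sinθ_x / λ, 2π sinθ_y / λ)`, `sinθ_x = x / √(x² + y² + z²)`.
The objective is a circular low-pass filter of radius `2π NA / λ` in the
spatial-frequency plane (the pupil); under tilted illumination it collects
the object-spectrum disk centred at `−k_m` (sign convention: an LED at `+x`
has `k_x > 0`; only the consistency of the sign pair between simulator and
reconstructor matters, and both use this one).  The synthesized aperture
after combining all LEDs reaches `NA_obj + NA_illum`.

Defocus by `z` µm multiplies the pupil interior by `exp(i z k_z)` with
`k_z = √((2πn/λ)² − |k|²)` and refractive index `n = 1` (air objective;
immersion is out of scope).  Chromatic effects, LED bandwidth, vignetting and
field-dependent aberrations are not modeled; one image tile is processed per
run.

Unit bookkeeping: one line pair (lp) is a full bright+dark period, so a bar
half-pitch `r` µm corresponds to `1000/(2r)` lp/mm; the coherent cutoff
`2πNA/λ` is reported in its engineering form `NA/λ` (lp/mm); Rayleigh
two-point resolution is `0.61 λ / NA`.  A nominally `M×` objective behind a
150 mm tube lens on the 180 mm Olympus reference standard magnifies
`M · 150/180` (≈3.3× and ≈8.3× for the 4× and 10× presets).  The
illumination NA of the default 15×15, 4 mm pitch, 70 mm distance array is
0.3714 along an axis and 0.4924 at the corners; the nominal figure 0.38 is
used for the equivalent-NA bookkeeping (0.48 and 0.63 for the two presets)
and both geometric maxima are always reported beside it.

## Forward model

Per LED: the object spectrum (FFT of `s`) is translated by `k_m` rounded to
whole spectrum pixels (the rounding residual is recorded in the stack
manifest; integer rounding keeps forward and inverse models consistent and
is standard FPM practice), multiplied by the possibly defocused pupil,
inverse transformed, and squared into an intensity image.  Camera pixels
integrate intensity: the high-resolution intensity is box-averaged by the
integer `downsample_factor`.  Exposure assumes equal LED radiance, scaled so
a clear field imaged on axis has mean 1.  Noise (Gaussian or Poisson) is off
by default and exists for robustness experiments.

Two modeling consequences are worth knowing.  First, box-averaging is not
point sampling: it attenuates intensity frequencies by a sinc factor (≤12 %
at the intensity band edge for the 4× preset) and offsets the effective
pixel centre by `(factor−1)/2` object pixels; the evaluator compensates for
the offset by widening bar regions of interest by up to one bar width.
Second, the grid-rounded `k_m` makes the FFT path *exactly* equal to the
brute-force oracle: an explicit dense-DFT implementation of the same
physics (tilted ramp, per-frequency pupil multiply, explicit inverse sums)
kept free of FFT routines and restricted to ≤64×64 objects; the two paths
agree to ~1e−15 RMS.

## Reconstruction (EPRY)

The high-resolution spectrum estimate lives on an `n·u × n·u` grid (`n` the
raw image side, `u` the integer upsampling factor), whose frequency sampling
equals the raw grid's, so each raw image maps to one `n × n` subregion
window centred at `−k_m`.  Initialization is the forward transform of the
Fourier-upsampled (zero-padded spectrum) square root of the on-axis
intensity with zero phase; the pupil starts as the ideal disk of the
configured NA.  Fourier (sinc) upsampling was chosen over bilinear because
it is exactly equivariant to circular shifts, which makes the whole pipeline
translation-covariant to machine precision — a property the test suite
checks directly.

Each sweep visits every subregion (default order: lowest `|k_m|` outward,
bright-field first) and applies three steps:

1. `Ψ_m = S_w P`, `ψ_m = F⁻¹[Ψ_m]/u²` (window times pupil, to the camera
   grid);
2. intensity constraint `φ_m = √I_m · ψ_m/|ψ_m|`, with phase factor 1 where
   `ψ_m = 0` — so `|φ_m|² = I_m` holds exactly, every visit;
3. regularized Gauss–Newton (EPRY-form) updates with `ΔΨ = u²F[φ_m] − Ψ_m`:

       S_w += conj(P)|P| / (max|P| (|P|² + δ₁)) · ΔΨ
       P   += conj(S_w°)|S_w°| / (max|S_w°| (|S_w°|² + δ₂)) · ΔΨ

   where `S_w°` is the pre-update window, `δ₁ = δ₂ = 1e−8·max|·|²` by
   default (configurable).  After each pupil step the pupil is re-clipped to
   the ideal-disk support and its magnitude capped at 1.

The per-sweep residual is the relative amplitude mismatch
`√(Σ(|ψ|−√I)² / ΣI)` accumulated with pre-update fields.  Iteration stops
after 50 sweeps or when the relative residual change drops below 1e−4
(both configurable; the tolerance is an engineering choice, no reference
value exists for it).  The output complex image is reported in a piston
gauge — the phase at the brightest amplitude pixel set to zero — because the
data leave the global phase unconstrained.

With the correct pupil on noiseless, model-consistent data the residual
decreases monotonically (asserted to 1e−12 slack over 30 sweeps); a
128×128 chromosome phantom is recovered to ≈0.02 relative RMS (complex,
global phase aligned), and a planted 10 µm defocus pupil is recovered with
phase correlation ≈0.94 over the disk after 50 sweeps of embedded pupil
recovery.

## Phantoms

**USAF target.**  Three-bar elements (bar length:width = 5:1, gap = width)
at any requested (group, element) pairs, both orientations, shelf-packed
into the field of view with ≥1 µm clearances.  Dark bars transmit
`1 − amplitude_contrast` and may carry a phase step (default 0: the physical
chart has no phase structure, which is the mode used for MTF work).  A
Nyquist guard requires ≥2 samples per half-pitch.  Rendering is 4×
supersampled then box-downsampled to avoid gridding artifacts in contrast
measurements; the machine-readable index records each element's rectangle
(µm) and frequency `2^(g+(e−1)/6)` lp/mm.

**Chromosome phantom.**  Elongated, slightly curved rods (quadratic Bézier
centerlines, default 4–9 µm long, 1.4 µm wide) with alternating dark/bright
bands perpendicular to the centerline — a linear spatial-frequency chirp
drawn from 200–800 lp/mm, below the ~1000 lp/mm regime of real G-band
patterns.  Bands are smooth cosine absorption profiles (dark-band minimum
transmission 0.35) with a proportional phase component (default 1 rad),
reflecting that Giemsa-stained chromatin is partly a phase object; the
contrast defaults are visual choices, not measured optical densities.
Ground truth records centerline, band boundaries along arclength, polarity,
and the frequency profile.  Generation is deterministic per seed; placements
that cannot avoid overlap raise after bounded retries.

The phantoms emulate geometry and banding, not cytology: no nuclei,
cytoplasm, debris, staining variability, or ISCN-accurate karyotypes.
Passing recovery tests therefore demonstrates correctness of the
computational chain under its own forward model — not performance on real
slides, where partial coherence, aberration fields, and sample thickness
enter.

## Resolving-power evaluation

Bar contrast is `C = (Imax − Imin)/(Imax + Imin)` with `Imin` the mean of
the three bar-centre extrema and `Imax` the mean of the two extrema between
them, measured on the length-averaged profile perpendicular to the bars
(the scale-invariant ratio form).  An element counts as *resolved* only if
the full extremum pattern is present with peak positions consistent with the
bar geometry up to a global registration shift; otherwise it contributes
contrast 0 with a not-resolved flag.  MTF samples over an element ladder are
normalized to the lowest-frequency element and fitted with a monotone
non-increasing curve (decreasing isotonic regression + monotone
piecewise-cubic interpolation by default; a logistic decay is available),
anchored to 1 at zero frequency.  The cutoff is the lowest frequency where
the fit reaches a configurable level, default 0.02 — fitted curves approach
zero only asymptotically — and is always reported with its level.

A caveat specific to *coherent* bar metrology: a finite three-bar pattern
just past the cutoff still shows placement-dependent edge-leakage ripple, so
the measured cutoff typically lands 10–25 % above `NA/λ` and the
smallest-resolved readout can sit one chart element past the Rayleigh
prediction.  Physical coherent systems behave the same way (a 0.1-NA
objective measures a cutoff near 237 lp/mm against a 189 lp/mm theory); the
tests therefore assert brackets (everything below the cutoff transfers,
everything two chart steps past is dead) rather than exact crossings.

## Desk-scale experiment sizes

All simulations are sized to run the full suite in about a minute on one
core while keeping every optical regime present: oracle comparisons on
32×32 objects; recovery experiments on 128×128 grids with the full 15×15
LED plan; USAF scenes on 112 (4×) and 168 (10×) raw camera pixels with 4×
camera integration, 4× reconstruction upsampling and ≤25 sweeps.  Under the
4× preset the on-axis image resolves group 7-3…7-5 while the reconstruction
resolves 9-5 (813 lp/mm, a ≥4× frequency gain); under the 10× preset the
readout jumps from 9-1 (512 lp/mm) to 10-3 (1290 lp/mm).  Reconstruction
from 0.1-NA data taken 20 µm out of focus retains ≈99 % of its in-focus bar
contrast, against ≈62 % for a simulated conventional 0.4-NA image — the
depth-of-field advantage that motivates low-NA acquisition.

## Known limitations

* Single tile, ideal LED positions, equal radiance; no self-calibration of
  LED positions and no adaptive defocus/wavefront search.
* Intensity box-averaging introduces a small model mismatch when
  `downsample_factor > 1`; the residual then plateaus near 1e−2 instead of
  vanishing.  Recovery-accuracy experiments use factor 1 (camera sampling at
  the simulation grid), where the model is exact.
* The MTF pipeline is bar-target-only (no slanted-edge or noise-target
  methods) and inherits the coherent-metrology caveats above.
* Reconstruction quality metrics are meaningful only relative to this
  forward model; no claim is made about matching the numerical MTF cutoffs
  of any physical instrument.
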