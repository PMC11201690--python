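# Methods note

This note records the models, conventions and numerical choices behind
`speckleflow`, and the known limitations of the synthetic generator.

## 1. Static speckle generator

Fully developed speckle is produced by the pupil-function method:

1. Draw an i.i.d. uniform phase per pixel and form the unit-modulus
   phasor field `exp(iφ)`.
2. Transform to the Fourier plane and apply a circular pupil (ideal
   low-pass) with cutoff `f_c` cycles/pixel.
3. Transform back; intensity is `|field|²`, rescaled to a mean of
   1000 counts (an arbitrary full-well-friendly scale), plus optional
   offset and Gaussian read noise.

This yields circular-Gaussian field statistics, hence
negative-exponential intensity and unit contrast — the canonical fully
developed limit.

**Grain-size calibration.** For a circular pupil the normalized field
correlation at lag `d` is `μ(d) = 2·J₁(2π f_c d)/(2π f_c d)` and the
intensity autocovariance is `|μ|²` (Siegert relation). The grain size
is defined as the FWHM of the intensity autocovariance, so the cutoff
is set to `f_c = z_half / (π · grain_size_px)` where `z_half ≈ 1.616`
solves `2·J₁(z)/z = 1/√2`. `z_half` is found once at import with
`scipy.optimize.brentq`; the calibration makes the *expected* FWHM
equal the requested grain exactly, with per-realization scatter of a
few percent on a 512×512 frame.

**Validity limits.** The config rejects grains below 2 px (sub-Nyquist:
the pupil would exceed the Fourier-plane radius) and warns when the
image is smaller than 8 grains per axis, where the FWHM estimate
becomes noisy.

## 2. Dynamic speckle and motion blur

Temporal decorrelation is modeled per Fourier mode: each mode inside
the pupil follows a stationary complex Ornstein–Uhlenbeck process,
`A ← ρA + √(1−ρ²)·ξ` with `ρ = exp(−Δt/τ)` and circular-Gaussian `ξ`.
All modes share one correlation time, giving a spatially homogeneous
dynamic pattern.

Conventions:

- `correlation_time_s` is the **field** correlation time τ. The
  intensity correlation time is τ/2 under the Siegert relation; users
  comparing to intensity-based literature values should halve
  accordingly.
- Motion blur is simulated by averaging 8 equally spaced sub-frames
  across the exposure window (`SUBFRAMES_PER_EXPOSURE = 8`). Eight is a
  compromise: it reproduces the contrast-versus-τ/T trend smoothly for
  τ ≳ 0.1·T, while keeping generation fast. For τ far below the
  sub-frame spacing the blur saturates at the 8-sample average
  (contrast floor ≈ 1/√8) instead of continuing toward 0.
- `correlation_time_s = inf` short-circuits to the static pattern, so
  a static stack is exactly frame-repeated.

The default acquisition parameters — 1250 frames/s, 0.8 ms exposure —
are typical high-speed settings for this class of measurement; the
default pixel pitch of 1.625 µm/px corresponds to a 6.5 µm sensor
pitch demagnified by a 4× objective. All are overridable per config.

## 3. Speckle size and contrast estimators

**Autocovariance.** Computed by Wiener–Khinchin on the mean-subtracted
frame, zero-padded to 2× per axis so the estimate is *linear* (not
circular), and normalized per lag by the overlap count
`(n−|Δr|)(m−|Δc|)` — an unbiased estimator. The map is then normalized
to 1 at zero lag. The unbiased normalization makes extreme-lag values
unreliable (few overlapping pixels), so downstream scans are restricted
to the central quarter of the lag range.

**FWHM.** Along each axis through the zero-lag peak, the half-maximum
crossing is located by walking outward and linearly interpolating
between the straddling samples; the per-axis FWHM is the sum of the
left and right half-widths, and the scalar speckle size is the mean of
the two axis widths (reported in px and, via the pixel pitch, µm). A
secondary maximum above half height inside the scanned range raises a
warning, since it indicates a non-speckle periodic structure. A peak
whose half level is not reached within the map is an error (field of
view too small for the grain).

**Contrast.** `C = sd/mean` with the sample standard deviation
(`ddof=1`), over a full frame or a rectangular ROI. Degenerate frames
(zero mean) yield NaN plus a flag in time series rather than an
exception, so one bad frame does not kill a sequence.

## 4. Front detection and flow speed

The front tracker assumes flow along one image axis with the dark
(unfilled) region ahead of the front:

1. Per frame, average intensity along the cross-flow axis to get a
   column profile.
2. Threshold at 0.5× a filled-region reference (the mean of the last
   frame's above-median columns); the front position is the farthest
   above-threshold column.
3. Median-filter the position trace (width 3) to suppress single-frame
   speckle flicker, then enforce monotonicity with a running maximum —
   a physical front never retreats in these assays.

Because the generator fills whole columns up to `floor(position)`, the
detector reports the last lit column, i.e. `floor(position) − 1`; this
≤2 px quantization is negligible over the 160–800 px ROIs used.

**Speed.** The ROI spans `roi_length_mm` (default 0.8 mm) starting at
`roi_start_px`. Entry/exit frames are the first frames where the front
reaches the ROI start/end, and
`speed = roi_length_mm × frame_rate / (exit − entry)`. Resolution is
one frame period, so the relative quantization error is ~1/(number of
frames in the crossing); the built-in simulations use ≈400 frames per
crossing, i.e. ≲0.5%. Fronts that never enter, stall inside the ROI, or
cross within a single frame raise `FrontDetectionError` with the last
observed position.

## 5. Fluorescence scoring

The relative fluorescence score has two modes:

- `literal`: `1 − A·I_b/I_s`, with `A` the signal area in pixels — the
  area-weighted form. Note it is unbounded below for large `A`.
- `normalized`: `1 − I_b/I_s`, dimensionless in (−∞, 1], the form
  suitable for comparing images of different sizes.

Segmentation uses Otsu's threshold (scikit-image); background is the
complement of the signal mask eroded by 3 px, so the dim halo at object
edges contaminates neither class. An empty mask warns and returns
`A = 0` rather than raising.

The synthetic fluorescence generator places flat-topped super-Gaussian
blobs (`exp(−(r²/2σ²)³)`) on a uniform background. The flat top makes
the ground-truth mask (half-maximum level set) insensitive to the exact
threshold, so segmentation accuracy can be scored by Jaccard overlap
without the truth definition itself being threshold-sensitive — a pure
Gaussian has no such natural boundary.

## 6. Statistics

- Group summaries: mean and sample SD (`ddof=1`; SD is `None` for
  n < 2).
- Pairwise comparison: Welch's unequal-variance t-test
  (`scipy.stats.ttest_ind(equal_var=False)`). Star labels use strict
  thresholds: `***` p < 0.001, `**` p < 0.01, `*` p < 0.05, else `NS`.
  Two zero-variance groups with equal means are reported as
  (p = 1, NS) rather than NaN.
- Trend fitting: ordinary least squares via `scipy.stats.linregress`.
  The predictor encoding (e.g. dilution index versus concentration) is
  an explicit, recorded field of the result, because the slope's
  meaning depends entirely on it.

## 7. Built-in demonstration experiment

`run_demo_experiment` simulates four conditions — platelet-poor and
whole blood, each ± ADP — with designed speckle sizes of
27.04 ± 1.24, 28.02 ± 0.46, 28.54 ± 0.72 and 32.89 ± 1.69 µm and flow
speeds of 0.32, 0.30, 0.27 and 0.025 mm/s. These targets are the
package's own demonstration design, chosen to be physiologically
plausible magnitudes for this assay class. Problem sizes are scaled for
speed: n = 10 size replicates and n = 3 flow runs per group, flow
frames of 48×200 px at a 5 µm/px effective pitch, with the frame rate
set adaptively so every crossing spans ≈400 frames. The analysis
pipeline measures everything blind to the ground truth.

## 8. Limitations

- The generator models speckle *statistics*, not blood: no hematology,
  coagulation kinetics, red-cell optics or channel geometry. Group
  differences are imposed via the designed grain/speed parameters.
- Single-scattering, fully developed, polarized speckle only; no
  partially developed patterns, multiple-scattering depolarization, or
  speckle from static + dynamic scatterer mixtures.
- Dynamics are isotropic and spatially homogeneous; real flow produces
  anisotropic, translating speckle with a velocity gradient across the
  channel.
- Motion blur uses 8 discrete sub-frames (contrast floor ≈ 1/√8 for
  τ ≪ exposure), and the temporal model is a single-τ OU process, not a
  flow-profile-derived spectrum.
- The front model fills sharp whole columns; real fronts have menisci,
  wall wetting and intensity gradients.
- Detector noise is additive Gaussian; no shot noise, fixed-pattern
  noise or saturation.
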