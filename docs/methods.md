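# Methods

This note records the models behind the synthetic scenes, the numerical
choices in the analysis chain, and what the synthetic benches do and do not
establish about real recordings.

## Image formation model

Frames are rendered from a fixed cloud of sub-resolution scatterers held in
material (frame-0) coordinates. Per frame the cloud is advected by the
scene's continuous displacement field, splatted onto the pixel grid with
bilinear weights, convolved with a separable Gaussian point-spread function
(default sigma 0.1 mm axial x 0.2 mm lateral), and log-compressed
(`255·log1p(αE/E₀)/log1p(α)`, α = 60, `E₀` the frame-0 envelope peak) to
8 bits. Motion is applied to continuous scatterer coordinates *before*
rasterisation, so sub-pixel displacements are rendered faithfully and
speckle decorrelates gradually under strain, as in real B-mode imaging.
There is no beamforming, attenuation, refraction or reverberation: the
point-spread function is shift-invariant and the speckle fully developed
only to the extent the default density (30 scatterers/mm²) allows.

Image axes: row = axial (depth), column = lateral, origin top-left; default
calibration 0.05 mm/pixel on both axes. All randomness flows from one
explicit seed through a single `numpy.random.Generator`; identical
parameters and seed reproduce bit-identical output.

### Spring scene

The spring axis lies along the axial direction; one end is fixed (at the
container base), the other driven so the length is
`L(t) = L₀ + (D/2)·sin(2πft)` exactly (default `L₀` = 10 mm). The
displacement field is an affine axial stretch about the fixed end — every
material point moves by `−s(t)·(y_fix − y)/L₀` — so the rendered end
structures (a lateral cap plus two short near-vertical edge segments per
end, with a frozen multiplicative texture along each polyline) have axial
centroids that track the ground truth exactly; a rendering-level audit
(`spring_structure_centroids`) confirms agreement within 0.02 mm. The
experiment preset crosses peak-to-peak amplitudes {0.4, 1.0, 1.4} mm with
frequencies {0.5, 0.7, 1, 2, 3, 5, 7, 8, 10} Hz, 30 s at 80 frames/s
(2400 frames per condition).

### Twitch scene

Two bright aponeurosis polylines (superficial at 3 mm depth, 14 mm resting
gap, slight lateral tilt) bound a speckled fascicle region. The twitch
waveform is a difference of two exponentials,
`a·(e^(−t/τ_decay) − e^(−t/τ_rise))` normalised to unit peak
(τ_rise 25 ms, τ_decay 90 ms, time-to-peak ≈ 44 ms), superposed per
stimulus at the stimulation rate (default 1 pps, 25 ms latency).

The displacement field is a phenomenological axial "accordion": piecewise
linear in material depth with plateaus at the aponeuroses and at the two
measurement rows (1/7 and 6/7 of the gap — exactly where the probe grid
reads off fascicle length). The superficial aponeurosis is fixed, the deep
one moves by the thickening amplitude, and the inner band between the
measurement rows contracts by the shortening amplitude, with the strain
absorbed symmetrically by the margin ramps. This construction makes muscle
length and thickness independently controllable and analytically exact —
`length(t) = L₀ − a_short·p(t)`, `thickness(t) = T₀ + a_thick·p(t)` — but it
is *not* a biomechanical pennation model: real fascicle geometry couples the
two. The plateaus (±T₀/14 around the measurement rows) exist so that linear
interpolation of tracked features is locally unbiased where the series are
measured; without them the kink at a displacement extremum biases any
piecewise-linear interpolant low.

### M-wave grid

Each channel of the 4-column x 8-row grid (10 mm spacing, column-major
numbering declared in every file header) receives a biphasic template —
first derivative of a Gaussian, 15 ms, 1 mV peak — scaled by a 2-D Gaussian
spatial profile centred between the middle columns (sigma 3 electrodes
along rows, 1.8 along columns), delayed by 0.5 ms per row of distance from
the profile centre, inserted at every trigger (first stimulus at 0.5 s,
spacing `fs/rate` samples), plus white noise (default 10 μV RMS), optional
powerline interference, and injectable failure modes: `open_contact`
(noise at 50x nominal), `short_circuit_pair` (bit-identical copy of the
same-column neighbour), `artifact_burst` (Hanning-windowed noise bursts).

### Interface signals

The electrode-skin interface is a lumped `R_series + (R_parallel ∥ C)`
network (defaults 1 kΩ, 1 MΩ, 4.7 nF); a two-electrode measurement lumps
two interfaces plus tissue in series, so magnitudes represent that series
total. Sweeps inject `(I_pp/2)·sin(2πft)` (200 nA peak-to-peak) at 10-1000
Hz, at least ten cycles per frequency, voltage-channel noise optional.

## Analysis chain: numerical choices

* **ROI tracking.** 10 x 15 px templates (10 rows axial — the spring edge
  structures extend laterally), exhaustive zero-normalized cross-correlation
  over a ±10 px window centred on the last estimate (the window tracks, so
  total excursion may exceed the margin), reference template from the first
  frame by default (no drift accumulation). Tie-break: first maximum in
  row-major order. Sub-pixel: separable parabolic vertex, clamped to
  (−0.5, 0.5); refinement is skipped at a numerically perfect peak, where
  the parabola would only add the autocorrelation-asymmetry bias. Frames
  with peak correlation below 0.5 are invalid and hold the last position.
* **NMSE.** Computed as written, no symmetrisation. For spring series both
  inputs are mean-removed first (they are *changes* in length and the
  absolute offset between image-derived and servo lengths is arbitrary); for
  M-wave templates no mean is removed (templates share a true zero baseline,
  and a DC contact artifact should count as error).
* **KLT.** Corners: minimum eigenvalue of the gradient structure tensor
  (`corner_shi_tomasi`, sigma 1.5), best-first with 6 px spacing, up to 300
  features; each aponeurosis band is topped up to 12 corners because the
  dense fascicle speckle otherwise monopolises the selection. Tracking:
  11 x 11 window, 3 pyramid levels, constant-Hessian iteration (template
  gradients), 12 iterations; features with anomalous residuals (> max(2.5x
  median, 6) intensity units) are re-localised by exhaustive ZNCC over
  ±12 px then LK-refined — this rescues the one fast frame per twitch
  (up to ~9 px/frame at the plateau rows) that exceeds the pyramid's
  convergence basin. Dropped features are replenished every frame. The
  defaults (300 features, 6 px spacing) were chosen because coarser
  settings leave Delaunay triangles straddling the displacement-profile
  transitions, biasing recovered shortening low by several percent.
* **Probe advection** is Lagrangian: per frame each probe moves by the
  interpolated incremental displacement of same-region features
  (barycentric inside the Delaunay hull — exact for affine fields — inverse
  distance over the 3 nearest outside); a probe with no usable
  interpolation holds its position that frame. Fascicle length uses the
  fascicle-region probe rows only, not the aponeurosis rows.
* **Filtering.** "4th-order noncausal Butterworth" is read as an order-4
  design applied forward-backward (zero phase, effective magnitude order
  8); the order-2-design alternative is selectable (`order=2`). Interface
  noise uses order 2, 10-1000 Hz, also zero-phase. Epochs start at the
  trigger sample; epoch length is `round(epoch_ms·fs/1000)` (82 samples for
  40 ms at 2048 Hz).
* **Impedance demodulation** fits `a·sin + b·cos + c` by least squares
  rather than reading an FFT bin, so sweep frequencies need not divide the
  record length. Phase is wrapped to (−180°, 180°].
* **Channel screening** runs on trigger-free background samples (100 ms
  blanked after each stimulus). Precedence: short-circuit (pair correlation
  > 0.999, RMS ratio within 1%), then powerline (> 50% of power in 45-65
  Hz — checked before the level rule because strong interference also
  inflates RMS), then open contact (RMS > 5x grid median), then artifact
  (background peak > 10x channel RMS).
* **Statistics.** Model II regression is reduced major axis
  (`slope = sign(r)·sd(y)/sd(x)`), chosen over major axis because the two
  tracking conditions carry comparable error. The factorial ANOVA is
  fixed-effects; with one observation per cell (the 27-condition bench)
  only main effects are estimable and interactions are omitted. A constant
  response reports F = 0, p = 1 rather than 0/0. The histogram KS test
  compares discrete empirical CDFs of the 256-bin mean histograms with the
  asymptotic p-value at effective n `√(n_a·n_b/(n_a+n_b))`; on binned data
  this is mildly conservative.
* **Degenerate inputs** are rejected, not repaired: zero-variance templates,
  all-zero NMSE references, measured noise below the amplifier floor
  (quadratic subtraction would need a negative radicand), frequencies at or
  above Nyquist, unsorted triggers, and channel counts that contradict the
  declared grid all raise typed errors.

## What the synthetic benches show — and what they do not

Passing benches establish that the *analysis chain* is correct and
self-consistent: tracking recovers known motion to small fractions of a
pixel, template averaging reduces noise as 1/√n, the impedance estimator
matches closed forms, and the statistics behave nominally under the null.
The synthetic scenes emulate geometry, kinematics, sampling rates and noise
levels of the acquisition protocol, but not out-of-plane motion, probe
pressure or repositioning, acoustic shadowing from conductive paste,
stimulation artifacts, motor-unit variability, or tissue inhomogeneity.
Error levels measured here are therefore lower bounds; the benches bound
the method's intrinsic error, not the error of a physical acquisition.
Tracking accuracy bounds are asserted against the published bench-top error
levels as upper bounds, not reproduced point by point.

## Problem sizes used

Unit tests run on short clips (0.25-2.5 s scenes, 2-8 s EMG records); the
protocol-scale checks use the full 30 s / 2400-frame oscillation trials and
20 s / 20-stimulus EMG trials. The twitch bench defaults to 10 s scenes;
calibration suites use 100-500 seeded replicates.
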