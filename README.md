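# echotrace

Validation pipeline for simultaneous high-density surface EMG and B-mode
ultrasound acquisition from the same muscle region.

Recording ultrasound images through a grid of surface electrodes only works
if the electrode material is acoustically transparent and the probe does not
degrade the electrophysiological signal. Establishing that requires a chain
of quantitative checks: can sub-millimetre tissue motion still be tracked in
the images? Are evoked compound muscle action potentials (M-waves) unchanged
when the probe sits on top of the electrode grid? Is the electrode-skin
interface electrically sound? `echotrace` implements that validation chain
as a reusable library, together with synthetic-scene generators that emit
every input with exact ground truth — so each quantitative claim can be
exercised end to end without hardware or human data.

## What it computes

**Spring-length tracking (in vitro emulation).** Eight 10 x 15 px regions of
interest placed on the edge structures at the two ends of an oscillating
spring are tracked frame by frame with zero-normalized cross-correlation;
the integer correlation peak is refined with a separable parabolic fit
(`d = (c₋ − c₊) / 2(c₋ − 2c₀ + c₊)`). Spring length is the distance between
the median centre positions of the two ROI groups, calibrated to mm. The
agreement between the predicted change `f(n)` and the imposed change `g(n)`
over `N` frames is the normalized mean square error

```
NMSE = 100 · Σₙ [f(n) − g(n)]² / Σₙ g(n)²   (%)
```

evaluated over the 3-amplitude x 9-frequency oscillation bench
(0.4/1.0/1.4 mm peak-to-peak; 0.5-10 Hz; 30 s at 80 frames/s).

**Twitch kinematics (in vivo emulation).** A Kanade-Lucas-Tomasi tracker
(minimum-eigenvalue corners, pyramidal Lucas-Kanade with drop-and-replenish)
feeds an 8 x 10 grid of measurement probes — outer rows on the aponeuroses,
inner six across the fascicle region — advected by Delaunay/barycentric
interpolation of same-region feature displacements. Muscle length
(deep-to-superficial fascicle probe distance) and thickness
(inter-aponeurosis distance) series from two recordings are aligned by
cross-correlation and compared with Pearson correlation and model II
(reduced major axis) regression, `slope = sign(r)·sd(y)/sd(x)`.

**M-wave templates.** Monopolar 32-channel grid recordings (4 columns x 8
rows, 2048 samples/s) are band-passed 20-450 Hz with a zero-phase Butterworth
filter; 40 ms epochs (82 samples) from each stimulation trigger are averaged
(20 consecutive M-waves) into per-channel templates, and the same NMSE
compares with-probe against without-probe templates channel by channel, with
group means for the central (probe footprint) and lateral electrode columns.
Automated screening flags open contacts, short-circuited pairs, powerline
contamination and movement artifacts.

**Electrode-skin interface.** Noise: band-pass 10-1000 Hz, RMS over the
acquisition, then quadratic subtraction of the amplifier noise floor
(`√(measured² − 0.8²)` μV). Impedance: per-frequency least-squares
demodulation of voltage/current sinusoid pairs over a 10-1000 Hz sweep,
validated against the closed-form lumped R-C interface model.

## Worked example

```python
import numpy as np
from echotrace.synthetic_data import SpringSceneParams, simulate_spring_sequence
from echotrace.roi_tracking import track_spring

params = SpringSceneParams(peak_to_peak_mm=1.0, frequency_hz=2.0,
                           duration_s=5.0, seed=1)
seq, truth = simulate_spring_sequence(params)      # rendered frames + exact truth
series, err = track_spring(seq, truth)             # 8-ROI pipeline

amp = (np.nanmax(series.length_mm) - np.nanmin(series.length_mm)) / 2
print(f"frames: {seq.n_frames}")
print(f"recovered amplitude: {amp:.4f} mm (imposed 0.5000 mm)")
print(f"NMSE vs imposed length change: {err:.3f} %")
```

prints

```
frames: 400
recovered amplitude: 0.5001 mm (imposed 0.5000 mm)
NMSE vs imposed length change: 0.003 %
```

i.e. the tracker recovers the imposed 0.5 mm oscillation amplitude to
0.1 μm-scale accuracy on this clean synthetic scene, and the residual error
between tracked and imposed length change is 0.003% of the imposed signal
power. The same chain is available from the shell:

```sh
echotrace simulate --scene spring --seed 1 --duration 5 --out clip
echotrace track-spring --images clip.tif --truth clip_gt.csv --out lengths.csv
echotrace spring-bench --seed 1 --out bench/     # full 27-condition table
echotrace mwave-bench  --seed 1 --out bench/     # 32-channel NMSE map
```

## Layout

```
src/echotrace/
  synthetic_data.py             scene/signal generators with ground truth
  containers.py, io_formats.py  core types; TIFF/CSV/JSON readers and writers
  roi_tracking.py               ZNCC ROI tracking, spring length, NMSE
  feature_tracking.py           KLT tracking, probe grid, twitch series
  emg_pipeline.py               filtering, epochs, templates, NMSE maps
  interface_characterization.py noise and impedance estimation
  image_stats.py                ROI intensity statistics, KS comparison
  stats.py                      model II regression, paired tests, ANOVA
  benches.py, cli.py            end-to-end benches and the echotrace CLI
docs/methods.md                 model assumptions, parameters, limitations
```
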