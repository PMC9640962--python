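# magmicro

Muscle-tissue length tracking from a wearable magnetometer array
(*magnetomicrometry*), for biomechanists and neuroprosthetics engineers who
need untethered, real-time muscle length signals.

Two small permanent-magnet beads are implanted in a muscle roughly 35 mm
apart. A skin-mounted planar grid of 96 three-axis magnetometers (8 × 12 at
5.08 mm pitch, sampled at 155 Hz) observes the superposed fields of the two
beads plus the ambient field. Each frame, the package solves the nonlinear
inverse problem

> minimize over (p₁, u₁, p₂, u₂, d):  Σₛ ‖ Bₛ − B_dip(sₛ; p₁, m u₁) −
> B_dip(sₛ; p₂, m u₂) − d ‖²

where `B_dip(r; p, m) = (μ₀/4π)(3(m·r̂)r̂ − m)/|r − p|³` is the point-dipole
field (exact for a uniformly magnetised sphere), `m = B_r πd³/6μ₀` is the
bead's moment magnitude, and `d` is a spatially uniform disturbance vector
that absorbs Earth's field and distant equipment. The reported signal is the
inter-bead distance `|p₁ − p₂|` in millimeters — the muscle tissue length
between the implants. Solves are damped least squares (Levenberg–Marquardt)
with an analytic Jacobian, warm-started from the previous frame; dropouts
shorter than 50 ms are bridged by linear interpolation, longer ones are
flagged as gaps.

The package also contains the validation machinery used to judge such a
tracker against a reference modality (biplanar X-ray "fluoromicrometry"):
time alignment by local or global offset search, R² (squared Pearson
correlation) and bias ± SD of the differences, subtraction of the
reference's manual-labeling noise variance, the benchtop 99th-percentile
error `e99`, gait-cycle segmentation and smoothing-spline summaries — plus a
fully ground-truthed simulator of gait trials, sensor noise, packet drops,
ambient-field rotation and the 40 mm benchtop fixture sweep, so everything
is testable end to end without animal data.

## Worked example

```python
import magmicro as mg

cfg = mg.SimConfig(duration=10.0, seed=1)        # defaults: 35 mm pair, 4.5 mm p-p gait,
truth = mg.gen_gait_trajectory(cfg)              # 0.15 µT sensor noise, packet drops,
stream = mg.sense(truth, cfg=cfg)                # rotating 50 µT ambient field

results = mg.MagnetTracker(stream).fit()
print(results.summary())

ref = mg.gen_reference(truth, labeling_noise_sd=0.098, offset=0.037)
fit = mg.LengthAgreement(results.lengths, ref).fit(method="local")
print(fit.summary())
```

prints

```
Magnet tracking results
===============================================
frames                      1550
tracked                     1544 ( 99.6 %)
length mean (mm)          34.577
length range (mm)         32.744 .. 37.257
residual RMS (T)       1.464e-07 (median)
solve time p50 (ms)        2.641
solve time p99 (ms)        6.447

Length agreement vs reference
=========================================
alignment offset (s)       0.035463
R^2                        0.996818
difference mean (mm)         0.0039
difference SD (mm)           0.0851
paired points                  1549
```

Reading the numbers: 6 of 1550 frames were lost to simulated packet drops
and bridged or flagged per the 50 ms rule; the tracked length swings ~4.5 mm
peak-to-peak around the 35 mm implant separation; the injected 37 ms clock
offset between tracker and reference is recovered to about a frame; and the
difference SD is dominated by the 0.098 mm labeling noise put into the
synthetic reference (slightly attenuated by interpolation at the fractional
recovered offset — see `docs/methods.md`). `mg.adjusted_sd(diff_sd,
label_sd)` removes a known labeling-noise variance from a difference SD,
e.g. `adjusted_sd(0.186, 0.098) → 0.158 mm`.

A CLI wraps the same operations:

```bash
magmicro simulate gait --config demo.yaml --out-frames frames.csv --out-truth truth.csv
magmicro track --frames frames.csv --out lengths.csv
magmicro validate --mm lengths.csv --ref ref.csv --report report.json
magmicro benchtop --report bench.json
magmicro run --config demo.yaml      # simulate → track → validate in one go
```

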