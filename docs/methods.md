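# Methods

This note documents the model, the estimation procedures, the synthetic
data generator and the numerical choices behind `magmicro`, in the spirit of
a package methods appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Forward model

Each of the two implanted beads is a uniformly magnetised NdFeB sphere.
Outside the sphere its field is *exactly* that of a point dipole at the
centre, so no finite-size or multipole corrections exist to be made; the
dipole model is not an approximation here. The moment magnitude is
`m = B_r · πd³/6 / μ₀`; with the default 3 mm diameter and a remanence of
1.40 T (a typical value for the N48-class material; the exact remanence of
any given bead lot is not published, and it only scales the field) this is
1.575 × 10⁻² A·m².

A frame of the 96-sensor array is modelled as

    B_s = R_s [ B_dip(x_s; p1, m u1) + B_dip(x_s; p2, m u2) + d ],

with `R_s` a per-sensor axis rotation (identity unless a hardware
calibration is supplied) and `d` a disturbance field assumed spatially
uniform across the ~56 mm array. This uniformity assumption is what lets a
single extra 3-vector absorb Earth's field, treadmill motors and X-ray
equipment; it fails only for ferromagnetic objects within a few
centimetres of the array, which is out of scope.

Coordinates: array frame, origin at the grid centre, x along the 12-sensor
edge, y along the 8-sensor edge, +z into the tissue, so bead depth is a
positive z. SI units internally; file readers convert declared µT/gauss/LSB
at the boundary.

## State, parameterisation and the solver

The per-frame state is 13-dimensional: two positions (3 + 3), two moment
directions (2 angles each) and `d` (3). Moment directions are stored as
unit vectors but *solved* as spherical angles so the optimizer is
unconstrained. The spherical chart is singular at its poles (∂u/∂φ → 0),
which in practice shows up as stalled convergence whenever a bead's moment
approaches the chart axis — the benchtop fixture, with both beads
magnetised along ẑ, sits exactly there. The solver therefore re-centres
the chart before every solve: each direction is expressed as
`u = Rᵀ u(θ, φ)` with `R` chosen to map the warm-start direction to the
equator (θ = π/2, φ = 0). Within-solve direction changes are always small,
so the chart never approaches its (rotated) poles.

The inner solve is Levenberg–Marquardt (MINPACK via
`scipy.optimize.least_squares`, `x_scale='jac'`) with the analytic Jacobian:
∂B/∂p from differentiating the dipole kernel, ∂B/∂(θ, φ) through the linear
map B = A(p)·m, and ∂B/∂d = I. Default tolerances `ftol 1e-15`,
`xtol 1e-12`, `gtol 1e-15` are deliberately tight: the residual is cheap
(288 values), warm starts converge in 2–4 evaluations anyway, and the slack
tolerance regime costs tracking precision on the noiseless fixtures used to
verify the pipeline. Warm solves are capped at 40 function evaluations,
cold refinements at 400. Non-convergence (or a solution crossing the array
plane, z ≤ 0) flags the frame unconverged; downstream it becomes a missing
sample.

Optional saturation masking drops any sensor with a component at or above a
configurable full-scale value (off by default: the simulator does not model
saturation, and at the default ≥ 10 mm depths the readings stay inside the
±1.6 mT range of the magnetometer class concerned).

### Cold start

Cold starts exploit the model's partial linearity: for a *fixed* candidate
position the field is linear in the moment vector, and subtracting the
across-array mean projects out the uniform term exactly. The search:

1. score every point of a coarse grid (5 mm lateral and depth steps, array
   footprint ± 20 mm laterally, 5–40 mm deep) by the residual of a 3-unknown
   linear fit of the demeaned frame;
2. keep the 12 best positions at least 7 mm apart (greedy non-maximum
   suppression);
3. re-score all pairs by a joint 6-unknown linear fit; refine the best 5
   pairs with the full nonlinear solver, moment directions seeded from the
   linear moment estimates, `d` from the mean field;
4. return the best refined state, labels ordered so bead 1 has the
   lexicographically smaller (x, y, z).

A frame whose demeaned RMS is below 1 nT carries no dipole information and
raises an initialization error rather than returning noise. This linear
scoring replaces a naive enumeration of candidate moment directions; it is
deterministic and strictly stronger (it solves the direction subproblem
exactly at each grid point).

### Stream tracking, labels, gaps, latency

Frames are tracked sequentially with warm starts; after a dropout of
≥ 250 ms the next valid frame is re-solved cold (warm basins comfortably
span the ≤ 50 ms gaps that are bridged at all, and 250 ms bounds the cost of
pathological streams). Bead identities are matched to the previous frame by
nearest neighbour, so labels never swap mid-stream. Missing runs (drops or
unconverged solves) shorter than 50 ms are filled by linear interpolation of
the *length* signal — not of the bead positions — and flagged `I`; runs of
50 ms or longer are flagged `G` and left empty. A run's span is measured as
`t_next_valid − t_prev_valid − 1/rate`, i.e. the time the signal was
actually absent. Per-frame solve wall times are recorded and reported as
nearest-rank order statistics (`ceil(q·n)`-th value); the same percentile
convention is used everywhere in the package, including e99.

## Validation statistics

* **Alignment.** `align_local` scans offsets at one-frame resolution inside
  a ±0.5 s window (the scale of sync-cable jitter), re-interpolating the
  reference at every candidate offset, then refines the minimum by bounded
  scalar search to < 0.1 ms. `align_global` first scans the full overlap at
  one-frame steps (for trials with no sync pulse at all); a non-periodic
  amplitude envelope in the signal is what disambiguates stride-period
  aliases. A near-flat objective (correlation < 0.2 at the optimum) emits
  an `AlignmentWarning` rather than failing.
* **Agreement.** The reference is linearly interpolated at the signal's
  time stamps, never extrapolated, and never interpolated across reference
  holes wider than 2.5 median sample intervals; signal gap samples are
  excluded. R² is the squared Pearson correlation — chosen over the
  identity-line 1 − SSres/SStot because published per-subject biases of
  ~0.5 mm coexist with R² ≥ 0.86, which is only consistent with the
  correlation definition. Differences are signal − reference.
* **Labeling noise.** With k ≥ 2 independent manual labelings of the same
  raw reference data: per-time-point sample variance (k − 1 denominator),
  averaged over time, square-rooted.
* **Adjusted SD.** `sqrt(diff_sd² − label_sd²)`; a label SD exceeding the
  difference SD is a domain error (the estimate would be imaginary). The
  end-to-end pipeline reports this error in its JSON output instead of
  aborting, because on synthetic data the condition arises legitimately —
  see "fractional-offset attenuation" below.
* **e99.** Nearest-rank 99th percentile of |length − nominal| over a
  benchtop sweep, rounded *up* to the nearest micrometer.
* **Segmentation / splines.** Strike-to-strike intervals are resampled onto
  a common [0, 1) phase grid; without event times, cycle windows fall back
  to successive signal peaks. Scatter summaries use a cubic smoothing
  spline in the classical convention where the smoothing parameter p
  multiplies the *fidelity* term (p = 1 interpolates); this maps to scipy's
  λ-penalty via λ = (1 − p)/p and is the convention in which the
  study-standard p = 0.8 is expressed. The spread curve is a same-p spline
  through squared residuals, square-rooted.

### Fractional-offset attenuation

Linear interpolation of a noisy reference at a fractional offset α averages
adjacent noise samples, shrinking the apparent noise variance by
(1 − α)² + α². When the true tracker error is far smaller than the
labeling noise — the usual synthetic regime, never the in-vivo one — the
MSE-minimising alignment exploits this and settles ~1–3 ms off the true
offset, leaving a difference SD a few percent *below* the injected labeling
SD. This is a property of the alignment estimator, not a bug in the
tracker; it is why the pipeline treats a failed variance subtraction as a
reportable condition, and why closure tests inject either labeling noise or
an offset, not both, when asserting exact recovery.

## The simulator

The generator emulates the study conditions, not turkey physiology:

* length signal `L(t) = 35 + 2.25·w(phase)` mm, with `w` a fixed
  two-harmonic stride waveform normalised to peak-to-peak 2 (≈ 4.5 mm
  peak-to-peak overall), per-cycle period jitter of 3 % SD, stride rate
  1.9 Hz by default (the treadmill-speed map `f = 1.5 + 0.4(v − 1.5)` Hz is
  provided), optional linear rate ramps and slow amplitude envelopes;
* bead pair along x, centred under the array, midpoint depth drawn once per
  trial from 11.2–26.6 mm (the depth range reported for the in-vivo
  recordings); soft-tissue artifact as band-limited (≤ 2 Hz) 3-D drift of
  the pair relative to the array, 2 mm peak by default; moment directions
  precessing at 3°/cycle;
* ambient field of 50 µT rotating at ≤ 0.2 Hz (body turns), or static, or
  with 5 µT steps (equipment), per config;
* i.i.d. Gaussian sensor noise, 0.15 µT SD per axis by default
  (magnetometer-class, not a published value);
* packet drops as a Poisson process (0.2 events/s) with exponential
  durations (mean 20 ms);
* a reference channel equal to the true length plus i.i.d. labeling noise
  (0.098 mm SD default, the published manual-labeling consistency), with an
  optional clock offset and removable windows;
* the benchtop fixture: a rigid 40 mm pair swept out-and-back along x then
  y at depths 10, 13.2, …, 29.2 mm (a ~1 cm minimum depth plus 3.2 mm plate
  increments, covering the observed 11.2–26.6 mm), beads magnetised along ẑ.

All randomness derives from one seed through SHA-named child streams, so
configurations reproduce bit-identically and adding a stochastic process
never perturbs the others.

What the simulator does **not** model — and therefore what passing tests do
not show about real data: sensor nonlinearity and miscalibration (the
dominant error source in practice), saturation, spatially non-uniform
disturbances, bead migration, wireless latency, and real muscle dynamics
(the waveform is a stand-in with matched amplitude and period only).
Noiseless closures demonstrate correctness of the estimator, not in-vivo
accuracy.

## Problem sizes

Default test and acceptance runs use 2–30 s gait streams (310–4650 frames)
and benchtop sweeps at 1–5 mm path steps (a few hundred frames); one
warm-started frame solves in a few milliseconds, a cold start in about a
second. These sizes make every statistic in the suite stable at the
asserted tolerances while keeping a full run under a minute of tracking.

## Known limitations

* Moment magnitude is fixed by the magnet spec; per-bead magnitude
  calibration is not estimated (the study does not state whether it was).
* The two-bead solver does not generalise to more magnets.
* The alignment objective is plain SSE over offset; in pathological
  periodic cases without an envelope, `align_global` can alias (documented
  behaviour, warned at low correlation).
* Latency figures measure this host's solve times; they support the
  percentile-reporting mechanism, not any published wall-clock value.
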