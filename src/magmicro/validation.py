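"""Agreement analysis between the magnetic length signal and a reference
modality: time alignment, R², difference statistics, labeling-noise
adjustment, benchtop percentile error, gait segmentation and spline
summaries.

Conventions, stated once because they matter downstream:

* R² is the squared Pearson correlation between the paired series (not an
  identity-line 1 − SSres/SStot), so a constant bias does not reduce it.
* Differences are signal − reference, so a negative mean means the magnetic
  signal reads short.
* Percentiles are nearest-rank (the ceil(q·n)-th order statistic) and the
  benchtop e99 is rounded *up* to the nearest micrometer.
* The labeling-noise estimator uses the k−1 variance denominator.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks
from scipy.stats import pearsonr

from .exceptions import AlignmentError, AlignmentWarning
from .streams import LengthSeries
from .tracker import nearest_rank_index


@dataclass
class AgreementReport:
    """Alignment offset and agreement statistics between two length series."""

    offset: float
    r2: float
    diff_mean: float
    diff_sd: float
    n_points: int
    adjusted_sd: float | None = None

    def as_dict(self) -> dict:
        out = {
            "offset_s": self.offset,
            "r2": self.r2,
            "diff_mean_mm": self.diff_mean,
            "diff_sd_mm": self.diff_sd,
            "n_points": self.n_points,
        }
        if self.adjusted_sd is not None:
            out["adjusted_sd_mm"] = self.adjusted_sd
        return out


@dataclass
class LabelingNoiseEstimate:
    """Manual-labeling noise: root of the time-averaged across-labeling variance."""

    sd: float
    n_labelings: int
    n_points: int


def _paired(
    mm: LengthSeries, ref: LengthSeries, offset: float = 0.0, max_ref_gap: float | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Values of mm and ref interpolated at mm's times shifted by ``offset``.

    Interpolation stays within the reference support: query times outside
    the reference range, or falling inside a reference hole wider than
    ``max_ref_gap``, are excluded, as are mm gap samples.
    """
    r = ref.dropna()
    if len(r) < 2:
        raise AlignmentError("reference series has fewer than 2 usable samples")
    if max_ref_gap is None:
        max_ref_gap = 2.5 * float(np.median(np.diff(r.t)))
    m_ok = mm.has_value & np.isfinite(mm.length_mm)
    tq = mm.t[m_ok] + offset
    inside = (tq >= r.t[0]) & (tq <= r.t[-1])
    # exclude queries inside wide reference holes
    idx = np.searchsorted(r.t, tq, side="right")
    idx = np.clip(idx, 1, len(r.t) - 1)
    hole = (r.t[idx] - r.t[idx - 1]) > max_ref_gap
    use = inside & ~hole
    if use.sum() < 2:
        raise AlignmentError("no overlapping support between the two series")
    vals_ref = np.interp(tq[use], r.t, r.length_mm)
    vals_mm = mm.length_mm[m_ok][use]
    return vals_mm, vals_ref, mm.t[m_ok][use]


def _mse_at(mm: LengthSeries, ref: LengthSeries, offset: float) -> float:
    try:
        a, b, _ = _paired(mm, ref, offset)
    except AlignmentError:
        return np.inf
    return float(np.mean((a - b) ** 2))


def align_local(mm: LengthSeries, ref: LengthSeries, window: float = 0.5) -> float:
    """Offset in ±``window`` s minimising the MSE between the series.

    The reference is re-interpolated at every candidate offset (a coarse
    one-frame grid scan, then bounded scalar refinement to < 0.1 ms).
    Positive offsets mean the reference clock lags.  A near-flat objective
    (correlation < 0.2 at the optimum) raises :class:`AlignmentWarning`.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    dt = float(np.median(np.diff(mm.t)))
    coarse = np.arange(-window, window + dt / 2, dt)
    costs = np.array([_mse_at(mm, ref, o) for o in coarse])
    if not np.isfinite(costs).any():
        raise AlignmentError("no overlapping support inside the alignment window")
    best = coarse[int(np.argmin(costs))]
    res = minimize_scalar(
        lambda o: _mse_at(mm, ref, o),
        bounds=(best - dt, best + dt),
        method="bounded",
        options={"xatol": 1e-5},
    )
    offset = float(res.x)
    a, b, _ = _paired(mm, ref, offset)
    if np.std(a) == 0 or np.std(b) == 0 or pearsonr(a, b).statistic < 0.2:
        warnings.warn(
            "alignment optimum is weakly determined (low correlation at best offset)",
            AlignmentWarning,
            stacklevel=2,
        )
    return offset


def align_global(mm: LengthSeries, ref: LengthSeries) -> float:
    """Exhaustive one-frame-step scan over the full overlap, then local refine.

    Used when no hardware sync pulse is available; an aperiodic amplitude
    envelope in the signal disambiguates the stride-period aliases.
    """
    dt = float(np.median(np.diff(mm.t)))
    r = ref.dropna()
    # o must place some mm query times inside the reference support
    lo = r.t[0] - mm.t[-1]
    hi = r.t[-1] - mm.t[0]
    if hi <= lo:
        raise AlignmentError("series do not overlap for any offset")
    # keep at least ~1 s of overlap to score a candidate
    guard = min(1.0, 0.45 * (hi - lo))
    coarse = np.arange(lo + guard, hi - guard + dt / 2, dt)
    if coarse.size == 0:
        coarse = np.array([0.5 * (lo + hi)])
    costs = np.array([_mse_at(mm, ref, o) for o in coarse])
    best = coarse[int(np.argmin(costs))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", AlignmentWarning)
        refine = minimize_scalar(
            lambda o: _mse_at(mm, ref, o),
            bounds=(best - 2 * dt, best + 2 * dt),
            method="bounded",
            options={"xatol": 1e-5},
        )
    return float(refine.x)


def agreement(
    mm: LengthSeries, ref_aligned: LengthSeries, offset: float = 0.0
) -> AgreementReport:
    """R² and difference statistics between aligned series.

    The reference is linearly interpolated at the signal's time points
    (within reference support only); gap samples are excluded.  Differences
    are signal − reference.
    """
    a, b, _ = _paired(mm, ref_aligned, offset)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant series")
    r = pearsonr(a, b).statistic
    diff = a - b
    return AgreementReport(
        offset=offset,
        r2=float(r**2),
        diff_mean=float(np.mean(diff)),
        diff_sd=float(np.std(diff, ddof=1)),
        n_points=int(len(diff)),
    )


def labeling_noise(labelings: list[LengthSeries]) -> LabelingNoiseEstimate:
    """Manual-processing noise from k ≥ 2 independent labelings of the same
    raw data: per-time-point sample variance (k−1 denominator) across the
    labelings, averaged over time, square-rooted."""
    if len(labelings) < 2:
        raise ValueError("need at least 2 labelings")
    t0 = labelings[0].t
    for s in labelings[1:]:
        if len(s) != len(t0) or not np.allclose(s.t, t0):
            raise ValueError("labelings must share the same time base")
    stack = np.vstack([s.length_mm for s in labelings])
    var = stack.var(axis=0, ddof=1)
    return LabelingNoiseEstimate(
        sd=float(np.sqrt(var.mean())), n_labelings=len(labelings), n_points=len(t0)
    )


def adjusted_sd(diff_sd: float, label_sd: float) -> float:
    """Variance subtraction: sqrt(diff_sd² − label_sd²), in mm.

    Removes the reference's manual-labeling noise from the raw difference SD
    to estimate the accuracy of the magnetic signal itself.
    """
    if label_sd < 0 or diff_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    if label_sd > diff_sd:
        raise ValueError(
            f"label_sd ({label_sd}) exceeds diff_sd ({diff_sd}); adjusted SD would be imaginary"
        )
    return math.sqrt(diff_sd**2 - label_sd**2)


def e99(measured: LengthSeries | np.ndarray, nominal: float) -> float:
    """99th-percentile absolute deviation from the fixture's nominal distance.

    Nearest-rank percentile, rounded up to the nearest micrometer; mm.
    """
    if isinstance(measured, LengthSeries):
        vals = measured.length_mm[measured.has_value]
    else:
        vals = np.asarray(measured, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no measured samples")
    err = np.sort(np.abs(vals - nominal))
    v = err[nearest_rank_index(0.99, err.size)]
    return math.ceil(v * 1e3 - 1e-9) / 1e3


def segment_gait(
    series: LengthSeries,
    toe_strikes: np.ndarray | list[float] | None = None,
    n_phase: int = 101,
) -> list[np.ndarray]:
    """Cut a length series into phase-normalised gait cycles.

    With ``toe_strikes`` (event times), each strike-to-strike interval is
    resampled onto a common phase grid [0, 1).  Without events, the cycle
    windows fall back to successive signal peaks (for recordings where only
    one strike was visible in the video).
    """
    s = series.dropna()
    if len(s) < 4:
        raise ValueError("series too short to segment")
    if toe_strikes is not None and len(toe_strikes) >= 2:
        events = np.sort(np.asarray(toe_strikes, dtype=float))
    else:
        dt = float(np.median(np.diff(s.t)))
        # conservative minimum cycle of 0.25 s keeps harmonics from splitting cycles
        peaks, _ = find_peaks(s.length_mm, distance=max(int(0.25 / dt), 1), prominence=0.25 * np.std(s.length_mm))
        if peaks.size < 2:
            raise ValueError("need at least two peaks for peak-based segmentation")
        events = s.t[peaks]
    segments = []
    phase = np.linspace(0.0, 1.0, n_phase, endpoint=False)
    for a, b in zip(events[:-1], events[1:]):
        if a < s.t[0] - 1e-12 or b > s.t[-1] + 1e-12:
            continue
        tq = a + phase * (b - a)
        segments.append(np.interp(tq, s.t, s.length_mm))
    if not segments:
        raise ValueError("no complete cycle inside the series support")
    return segments


@dataclass
class SplineSummary:
    """Smoothed mean and spread of phase-scattered length data."""

    phase: np.ndarray
    curve: np.ndarray
    sd: np.ndarray


def spline_summary(
    phase: np.ndarray,
    length: np.ndarray,
    p: float = 0.8,
    grid: np.ndarray | None = None,
) -> SplineSummary:
    """Cubic smoothing spline summary of (phase, length) scatter.

    Uses the classical penalized-least-squares form in which the smoothing
    parameter ``p`` multiplies the fidelity term,

        p · Σ w_i (y_i − f(x_i))² + (1 − p) · ∫ f″(x)² dx ,

    (so p = 1 interpolates and p → 0 tends to the least-squares line); this
    is the convention in which the study-standard value p = 0.8 is
    expressed, and maps onto scipy's λ-penalty via λ = (1 − p)/p.  The
    spread curve is a same-p spline through the squared residuals,
    square-rooted (a smoothed root-mean-square).
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    x = np.asarray(phase, dtype=float)
    y = np.asarray(length, dtype=float)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    # merge duplicate abscissae with weights (the penalized fit needs strict order)
    ux, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
    if ux.size < 4:
        raise ValueError("need at least 4 distinct phase values")
    uy = np.zeros_like(ux)
    np.add.at(uy, inv, y)
    uy /= counts
    w = counts.astype(float)
    lam = (1.0 - p) / p
    spl = make_smoothing_spline(ux, uy, w=w, lam=lam)
    resid = y - spl(x)
    usq = np.zeros_like(ux)
    np.add.at(usq, inv, resid**2)
    usq /= counts
    spl_var = make_smoothing_spline(ux, usq, w=w, lam=lam)
    if grid is None:
        grid = np.linspace(ux[0], ux[-1], 201)
    return SplineSummary(
        phase=grid,
        curve=spl(grid),
        sd=np.sqrt(np.clip(spl_var(grid), 0.0, None)),
    )


class LengthAgreement:
    """Agreement model between a tracked length signal and a reference series.

    Statsmodels-style: construct from the two series, :meth:`fit` aligns
    them (locally inside a window, or globally when no sync is available)
    and returns an :class:`AgreementResults`.
    """

    def __init__(self, signal: LengthSeries, reference: LengthSeries, window: float = 0.5):
        self.signal = signal
        self.reference = reference
        self.window = window

    def fit(self, method: str = "local", label_sd: float | None = None) -> "AgreementResults":
        if method == "local":
            offset = align_local(self.signal, self.reference, self.window)
        elif method == "global":
            offset = align_global(self.signal, self.reference)
        elif method == "none":
            offset = 0.0
        else:
            raise ValueError(f"unknown alignment method {method!r}")
        report = agreement(self.signal, self.reference, offset=offset)
        if label_sd is not None:
            report.adjusted_sd = adjusted_sd(report.diff_sd, label_sd)
        return AgreementResults(self, report)


class AgreementResults:
    """Fitted agreement: offset, R², bias ± SD, optional noise-adjusted SD."""

    def __init__(self, model: LengthAgreement, report: AgreementReport):
        self.model = model
        self.report = report

    @property
    def offset(self) -> float:
        return self.report.offset

    @property
    def r2(self) -> float:
        return self.report.r2

    @property
    def diff_mean(self) -> float:
        return self.report.diff_mean

    @property
    def diff_sd(self) -> float:
        return self.report.diff_sd

    def adjusted(self, label_sd: float) -> float:
        return adjusted_sd(self.report.diff_sd, label_sd)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Length agreement vs reference",
            "=" * 41,
            f"alignment offset (s)   {r.offset:>12.6f}",
            f"R^2                    {r.r2:>12.6f}",
            f"difference mean (mm)   {r.diff_mean:>12.4f}",
            f"difference SD (mm)     {r.diff_sd:>12.4f}",
            f"paired points          {r.n_points:>12d}",
        ]
        if r.adjusted_sd is not None:
            lines.append(f"adjusted SD (mm)       {r.adjusted_sd:>12.4f}")
        return "\n".join(lines)
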