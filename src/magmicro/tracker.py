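"""Per-frame inverse solver: field frames -> bead positions -> muscle length.

Each frame is solved by damped nonlinear least squares (Levenberg–Marquardt
via MINPACK) over the 13-parameter state ``[p1, θ1, φ1, p2, θ2, φ2, d]``,
minimising the summed squared difference between measured and modelled
sensor readings.  Consecutive frames warm-start at the previous solution,
which keeps the per-frame solve to a handful of iterations; cold starts use
a deterministic coarse grid search exploiting the fact that, for fixed bead
positions, the model is linear in the moment vectors and the disturbance.

The per-sample gap policy follows the wireless packet-drop handling of the
wearable system: dropouts shorter than 50 ms are bridged by linear
interpolation of the length signal and flagged ``I``; longer runs are
flagged ``G`` and left empty.
"""
from __future__ import annotations

import itertools
import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .exceptions import InitializationError
from .geometry import MagnetSpec, SensorArray, make_grid_array
from .physics import (
    N_PARAMS,
    PhysicalState,
    dipole_design_matrix,
    dipole_position_jacobian,
    forward,
    sph_tangents,
    unit_from_angles,
)
from .streams import FieldFrame, FieldStream, GapFlag, LengthSeries


@dataclass(frozen=True)
class TrackerConfig:
    """Solver and stream-handling settings.

    Tolerances are passed straight to the damped least-squares solver;
    ``gap_threshold`` (seconds) separates interpolated from abandoned
    dropouts, and ``reinit_after`` forces a fresh cold start once the track
    has been lost for that long.  ``full_scale`` (tesla, per axis) marks
    saturated sensors invalid; None disables saturation masking.
    """

    ftol: float = 1e-15
    xtol: float = 1e-12
    gtol: float = 1e-15
    max_iter_warm: int = 40
    max_iter_cold: int = 400
    gap_threshold: float = 0.050
    reinit_after: float = 0.250
    full_scale: float | None = None
    max_residual_rms: float | None = None  # tesla; reject fits worse than this


@dataclass(frozen=True)
class InitConfig:
    """Cold-start grid-search settings (meters)."""

    lateral_margin: float = 0.020
    depth_min: float = 0.005
    depth_max: float = 0.040
    lateral_step: float = 0.005
    depth_step: float = 0.005
    top_positions: int = 12
    min_separation: float = 0.007
    top_pairs: int = 5
    min_signal: float = 1e-9  # tesla RMS of the demeaned frame


@dataclass
class TrackerState:
    """One frame's solution plus solver diagnostics."""

    physical: PhysicalState
    residual_rms: float
    iterations: int
    converged: bool
    solve_time: float
    t: float = float("nan")
    n_sensors_used: int = 0


def bead_distance(state: TrackerState) -> float:
    """Inter-bead distance in millimeters — the muscle tissue length signal."""
    return state.physical.separation_mm()


def _order_beads(state: PhysicalState) -> PhysicalState:
    """Deterministic labels: bead 1 has the smaller (x, y, z) lexicographically."""
    if tuple(state.p1) <= tuple(state.p2):
        return state
    return replace(state, p1=state.p2, p2=state.p1, u1=state.u2, u2=state.u1)


def _match_labels(state: PhysicalState, prev: PhysicalState) -> PhysicalState:
    """Keep bead identities continuous: nearest-neighbour match to ``prev``."""
    keep = np.linalg.norm(state.p1 - prev.p1) + np.linalg.norm(state.p2 - prev.p2)
    swap = np.linalg.norm(state.p1 - prev.p2) + np.linalg.norm(state.p2 - prev.p1)
    if swap < keep:
        return replace(state, p1=state.p2, p2=state.p1, u1=state.u2, u2=state.u1)
    return state


def _sensor_mask(frame: FieldFrame, cfg: TrackerConfig) -> np.ndarray:
    fields = frame.fields
    mask = np.all(np.isfinite(fields), axis=1)
    if cfg.full_scale is not None:
        mask &= np.all(np.abs(fields) < cfg.full_scale, axis=1)
    return mask


def _rotation_to_equator(u: np.ndarray) -> np.ndarray:
    """Rotation R with R @ u = x̂, used to re-centre the moment-angle chart.

    The spherical chart (θ, φ) is singular at its poles; solving in a chart
    rotated so the warm-start direction sits on the equator keeps both angle
    derivatives full-rank for any attitude the beads may take.
    """
    xhat = np.array([1.0, 0.0, 0.0])
    v = np.cross(u, xhat)
    s = np.linalg.norm(v)
    c = float(u @ xhat)
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        return np.diag([-1.0, -1.0, 1.0])  # u = −x̂: rotate π about z
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def _solve(
    state0: PhysicalState,
    meas: np.ndarray,
    spec: MagnetSpec,
    array: SensorArray,
    cfg: TrackerConfig,
    max_iter: int,
) -> tuple[PhysicalState, float, int, bool]:
    """One Levenberg–Marquardt solve warm-started at ``state0``.

    Returns (state, residual_rms, nfev, ok).  Moment directions are solved
    in charts rotated so the start direction lies on the equator (θ = π/2,
    φ = 0), avoiding the polar singularity of the angle parameterisation.
    """
    target = meas.ravel()
    m_mag = spec.moment_magnitude
    R1 = _rotation_to_equator(state0.u1)
    R2 = _rotation_to_equator(state0.u2)
    x0 = np.concatenate(
        [state0.p1, [np.pi / 2, 0.0], state0.p2, [np.pi / 2, 0.0], state0.d]
    )

    def x_to_state(x: np.ndarray) -> PhysicalState:
        return PhysicalState(
            p1=x[0:3],
            u1=R1.T @ unit_from_angles(x[3], x[4]),
            p2=x[5:8],
            u2=R2.T @ unit_from_angles(x[8], x[9]),
            d=x[10:13],
        )

    def fun(x: np.ndarray) -> np.ndarray:
        return forward(x_to_state(x), spec, array).ravel() - target

    def jac(x: np.ndarray) -> np.ndarray:
        sensors = array.positions
        n = sensors.shape[0]
        J = np.zeros((n, 3, N_PARAMS))
        for bead, (R, c) in enumerate(((R1, 0), (R2, 5))):
            th, ph = x[c + 3], x[c + 4]
            u = R.T @ unit_from_angles(th, ph)
            p = x[c : c + 3]
            dudth, dudph = sph_tangents(th, ph)
            dBdm = dipole_design_matrix(sensors, p)
            J[:, :, c : c + 3] = dipole_position_jacobian(sensors, p, m_mag * u)
            J[:, :, c + 3] = dBdm @ (m_mag * (R.T @ dudth))
            J[:, :, c + 4] = dBdm @ (m_mag * (R.T @ dudph))
        J[:, :, 10:13] = np.eye(3)
        if not array.identity_axes:
            J = np.einsum("nij,njk->nik", array.axis_map, J)
        return J.reshape(3 * n, N_PARAMS)

    res = least_squares(
        fun,
        x0,
        jac=jac,
        method="lm",
        ftol=cfg.ftol,
        xtol=cfg.xtol,
        gtol=cfg.gtol,
        max_nfev=max_iter,
        x_scale="jac",
    )
    rms = float(np.sqrt(np.mean(res.fun**2)))
    ok = res.status > 0
    return x_to_state(res.x), rms, int(res.nfev), ok


def track_frame(
    prev: TrackerState,
    frame: FieldFrame,
    spec: MagnetSpec,
    array: SensorArray,
    cfg: TrackerConfig | None = None,
) -> TrackerState:
    """Warm-started solve of one frame from the previous frame's solution."""
    cfg = cfg or TrackerConfig()
    if not frame.valid:
        raise ValueError("cannot track an invalid (dropped) frame")
    t0 = time.perf_counter()
    mask = _sensor_mask(frame, cfg)
    sub = array.subset(mask) if not mask.all() else array
    meas = frame.fields[mask]
    st, rms, nfev, ok = _solve(prev.physical, meas, spec, sub, cfg, cfg.max_iter_warm)
    state = _match_labels(st, prev.physical)
    converged = ok and state.p1[2] > 0 and state.p2[2] > 0
    if cfg.max_residual_rms is not None and rms > cfg.max_residual_rms:
        converged = False
    return TrackerState(
        physical=state,
        residual_rms=rms,
        iterations=nfev,
        converged=converged,
        solve_time=time.perf_counter() - t0,
        t=frame.t,
        n_sensors_used=int(mask.sum()),
    )


def _grid_candidates(array: SensorArray, icfg: InitConfig) -> np.ndarray:
    span_x, span_y = array.span()
    hx = span_x / 2 + icfg.lateral_margin
    hy = span_y / 2 + icfg.lateral_margin
    xs = np.arange(-hx, hx + 1e-12, icfg.lateral_step)
    ys = np.arange(-hy, hy + 1e-12, icfg.lateral_step)
    zs = np.arange(icfg.depth_min, icfg.depth_max + 1e-12, icfg.depth_step)
    g = np.array(list(itertools.product(xs, ys, zs)))
    return g


def initialize(
    frame: FieldFrame,
    spec: MagnetSpec,
    array: SensorArray,
    cfg: TrackerConfig | None = None,
    init_cfg: InitConfig | None = None,
) -> TrackerState:
    """Cold start: deterministic coarse search then local refinement.

    For a fixed candidate position the model is linear in the moment vector
    and the uniform disturbance, so each grid point is scored by a small
    linear least-squares fit after removing the per-axis mean (which absorbs
    d exactly).  The best-separated single-bead candidates are paired, pairs
    are re-scored by a joint linear fit, and the top pairs are refined by the
    full nonlinear solver; the best refined state wins.  Bead labels are
    assigned by the lexicographic (x, y, z) tie-break.
    """
    cfg = cfg or TrackerConfig()
    icfg = init_cfg or InitConfig()
    if not frame.valid:
        raise ValueError("cannot initialize from an invalid frame")
    t0 = time.perf_counter()
    mask = _sensor_mask(frame, cfg)
    sub = array.subset(mask) if not mask.all() else array
    meas = frame.fields[mask]
    n = meas.shape[0]
    mean_field = meas.mean(axis=0)
    f0 = meas - mean_field  # uniform component projected out
    if np.sqrt(np.mean(f0**2)) < icfg.min_signal:
        raise InitializationError("frame carries no dipole signal above the uniform field")

    grid = _grid_candidates(sub, icfg)
    y = f0.ravel()
    costs = np.empty(len(grid))
    mats = []
    for i, p in enumerate(grid):
        A = dipole_design_matrix(sub.positions, p)  # (n, 3, 3)
        Ad = (A - A.mean(axis=0)).reshape(3 * n, 3)
        m_hat, res, *_ = np.linalg.lstsq(Ad, y, rcond=None)
        costs[i] = res[0] if res.size else float(np.sum((Ad @ m_hat - y) ** 2))
        mats.append(Ad)

    # non-maximum suppression: greedily keep well-separated best positions
    order = np.argsort(costs)
    picked: list[int] = []
    for idx in order:
        if all(np.linalg.norm(grid[idx] - grid[j]) >= icfg.min_separation for j in picked):
            picked.append(int(idx))
        if len(picked) >= icfg.top_positions:
            break

    pair_scores = []
    for a, b in itertools.combinations(picked, 2):
        if np.linalg.norm(grid[a] - grid[b]) < icfg.min_separation:
            continue
        Ad = np.hstack([mats[a], mats[b]])
        m_hat, res, *_ = np.linalg.lstsq(Ad, y, rcond=None)
        cost = res[0] if res.size else float(np.sum((Ad @ m_hat - y) ** 2))
        pair_scores.append((cost, a, b, m_hat))
    if not pair_scores:
        raise InitializationError("no candidate bead pair found")
    pair_scores.sort(key=lambda s: s[0])

    m_mag = spec.moment_magnitude
    best: TrackerState | None = None
    for cost, a, b, m_hat in pair_scores[: icfg.top_pairs]:
        m1, m2 = m_hat[:3], m_hat[3:]
        if np.linalg.norm(m1) < 1e-12 or np.linalg.norm(m2) < 1e-12:
            continue
        state0 = PhysicalState(
            p1=grid[a],
            p2=grid[b],
            u1=m1 / np.linalg.norm(m1),
            u2=m2 / np.linalg.norm(m2),
            d=mean_field,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # coarse seeds may transiently overflow
            st, rms, nfev, ok = _solve(state0, meas, spec, sub, cfg, cfg.max_iter_cold)
        if not ok or st.p1[2] <= 0 or st.p2[2] <= 0:
            continue
        if best is None or rms < best.residual_rms:
            best = TrackerState(
                physical=_order_beads(st),
                residual_rms=rms,
                iterations=nfev,
                converged=True,
                solve_time=0.0,
                t=frame.t,
                n_sensors_used=n,
            )
    if best is None:
        raise InitializationError("no cold-start candidate converged")
    if cfg.max_residual_rms is not None and best.residual_rms > cfg.max_residual_rms:
        raise InitializationError(
            f"best cold-start residual {best.residual_rms:.3e} T exceeds the limit"
        )
    best.solve_time = time.perf_counter() - t0
    return best


def track_stream(
    stream: FieldStream,
    spec: MagnetSpec,
    array: SensorArray,
    cfg: TrackerConfig | None = None,
    init_cfg: InitConfig | None = None,
) -> tuple[LengthSeries, list[TrackerState | None]]:
    """Track a whole stream; returns the gap-annotated length series.

    Dropped or unconverged frames become missing samples.  Missing runs whose
    span is below the gap threshold are linearly interpolated in the length
    signal (not in bead positions) and flagged ``I``; longer runs are flagged
    ``G``.  After the track has been lost for ``reinit_after`` seconds the
    next valid frame is re-solved from a cold start.
    """
    cfg = cfg or TrackerConfig()
    n = len(stream)
    if n == 0 or not stream.valid.any():
        raise ValueError("stream contains no valid frames")
    states: list[TrackerState | None] = [None] * n
    last_idx: int | None = None
    for i in range(n):
        if not stream.valid[i]:
            continue
        frame = stream.frame(i)
        st: TrackerState | None = None
        cold = last_idx is None or (stream.t[i] - stream.t[last_idx]) >= cfg.reinit_after
        if not cold:
            st = track_frame(states[last_idx], frame, spec, array, cfg)  # type: ignore[arg-type]
            if not st.converged:
                st = None
        if st is None:
            try:
                st = initialize(frame, spec, array, cfg, init_cfg)
            except InitializationError:
                st = None
        if st is not None and st.converged:
            if last_idx is not None:
                st.physical = _match_labels(st.physical, states[last_idx].physical)  # type: ignore[union-attr]
            states[i] = st
            last_idx = i

    dt = 1.0 / stream.rate
    length = np.full(n, np.nan)
    flags = np.full(n, GapFlag.GAP.value, dtype="<U1")
    for i, st in enumerate(states):
        if st is not None:
            length[i] = bead_distance(st)
            flags[i] = GapFlag.MEASURED.value

    # classify missing runs
    good = np.flatnonzero(flags == GapFlag.MEASURED.value)
    if good.size == 0:
        raise ValueError("no frame in the stream could be tracked")
    for a, b in zip(good[:-1], good[1:]):
        if b - a <= 1:
            continue
        span = (stream.t[b] - stream.t[a]) - dt  # duration of the missing run
        idx = np.arange(a + 1, b)
        if span < cfg.gap_threshold:
            length[idx] = np.interp(stream.t[idx], [stream.t[a], stream.t[b]], [length[a], length[b]])
            flags[idx] = GapFlag.INTERPOLATED.value
        else:
            flags[idx] = GapFlag.GAP.value
    return LengthSeries(stream.t.copy(), length, flags), states


def latency_report(states: list[TrackerState | None]) -> dict[str, float]:
    """Order statistics of per-frame solve times (nearest-rank percentiles)."""
    times = np.sort([s.solve_time for s in states if s is not None])
    if times.size == 0:
        raise ValueError("no tracked states to report on")
    return {
        "percentile_99": float(times[nearest_rank_index(0.99, times.size)]),
        "median": float(times[nearest_rank_index(0.50, times.size)]),
        "n": int(times.size),
    }


def nearest_rank_index(q: float, n: int) -> int:
    """0-based index of the nearest-rank q-th percentile: ceil(q·n)-th order stat."""
    if not 0 < q <= 1:
        raise ValueError("q must be in (0, 1]")
    return max(int(np.ceil(q * n)) - 1, 0)


class MagnetTracker:
    """Two-bead tracking model over a recorded or simulated field stream.

    Statsmodels-style surface: construct from data, then :meth:`fit` returns
    a :class:`TrackingResults` carrying the length series, per-frame states
    and diagnostics.

    Parameters
    ----------
    stream : FieldStream
        Timestamped sensor frames (tesla, array frame).
    array : SensorArray, optional
        Defaults to the 8×12 grid at 5.08 mm pitch.
    magnet : MagnetSpec, optional
        Defaults to a 3 mm N48-class bead.
    config, init_config : solver settings.
    """

    def __init__(
        self,
        stream: FieldStream,
        array: SensorArray | None = None,
        magnet: MagnetSpec | None = None,
        config: TrackerConfig | None = None,
        init_config: InitConfig | None = None,
    ) -> None:
        self.stream = stream
        self.array = array or make_grid_array()
        self.magnet = magnet or MagnetSpec()
        self.config = config or TrackerConfig()
        self.init_config = init_config or InitConfig()

    def fit(self) -> "TrackingResults":
        lengths, states = track_stream(
            self.stream, self.magnet, self.array, self.config, self.init_config
        )
        return TrackingResults(self, lengths, states)


class TrackingResults:
    """Fitted track: length series, per-frame states, latency diagnostics."""

    def __init__(
        self,
        model: MagnetTracker,
        lengths: LengthSeries,
        states: list[TrackerState | None],
    ) -> None:
        self.model = model
        self.lengths = lengths
        self.states = states

    @property
    def n_frames(self) -> int:
        return len(self.lengths)

    @property
    def n_tracked(self) -> int:
        return sum(s is not None for s in self.states)

    def latency_report(self) -> dict[str, float]:
        return latency_report(self.states)

    def summary(self) -> str:
        lat = self.latency_report()
        vals = self.lengths.length_mm[self.lengths.measured]
        rms = np.array([s.residual_rms for s in self.states if s is not None])
        lines = [
            "Magnet tracking results",
            "=" * 47,
            f"frames                {self.n_frames:>10d}",
            f"tracked               {self.n_tracked:>10d}"
            f" ({100.0 * self.n_tracked / self.n_frames:5.1f} %)",
            f"length mean (mm)      {np.mean(vals):>10.3f}",
            f"length range (mm)     {np.min(vals):>10.3f} .. {np.max(vals):.3f}",
            f"residual RMS (T)      {np.median(rms):>10.3e} (median)",
            f"solve time p50 (ms)   {1e3 * lat['median']:>10.3f}",
            f"solve time p99 (ms)   {1e3 * lat['percentile_99']:>10.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Length trace with interpolated spans dashed and gaps omitted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ls = self.lengths
        shown = np.where(ls.has_value, ls.length_mm, np.nan)
        ax.plot(ls.t, shown, lw=0.8, label="MM length")
        interp = np.where(ls.flags == GapFlag.INTERPOLATED.value, ls.length_mm, np.nan)
        ax.plot(ls.t, interp, lw=0.8, ls="--", color="gray", label="interpolated")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("length (mm)")
        ax.legend(frameon=False)
        return ax
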