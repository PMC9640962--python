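"""Ground-truthed synthetic data: gait trajectories, sensor streams, an
X-ray-like reference channel, and the benchtop fixture sweep.

The generator emulates the study conditions of treadmill locomotion sensing:
a two-bead pair implanted ~35 mm apart, a muscle-length waveform of ~4.5 mm
peak-to-peak at stride rates mapped from treadmill speed, bead depths inside
11.2–26.6 mm, slow soft-tissue drift of the bead pair relative to the skin-
mounted array, an Earth-scale ambient field that rotates as the subject
turns, magnetometer-class white noise, and wireless packet drops.

All randomness flows from a single top-level seed through named child
streams, so adding one stochastic process never perturbs the others and a
fixed config reproduces bit-identical output.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError
from .geometry import MagnetSpec, SensorArray, make_grid_array
from .physics import PhysicalState, forward
from .streams import FieldStream, GapFlag, LengthSeries


@dataclass(frozen=True)
class DropoutConfig:
    """Wireless packet-drop process: Poisson event starts, exponential spans."""

    rate: float = 0.2  # events per second
    mean_duration: float = 0.020  # seconds


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic gait generator.

    Lengths in millimeters, rates in Hz, fields in tesla.
    """

    duration: float = 10.0
    rate: float = 155.0
    base_length: float = 35.0  # target implant separation, 3.5 cm
    pp_amplitude: float = 4.5  # average signal magnitude, peak-to-peak
    gait_freq: float = 1.9  # stride rate at a 2.5 m/s treadmill speed
    gait_freq_end: float | None = None  # linear ramp target (None = constant)
    cycle_jitter: float = 0.03  # per-cycle fractional period jitter
    depth_range: tuple[float, float] = (11.2, 26.6)  # observed tracking depths
    artifact_amplitude: float = 2.0  # soft-tissue drift of the pair, mm
    artifact_max_freq: float = 2.0  # Hz
    precession_deg_per_cycle: float = 3.0  # slow moment-direction drift
    disturbance_model: str = "slow-rotation"  # static | slow-rotation | steps
    disturbance_magnitude: float = 50e-6  # Earth-scale ambient field, T
    disturbance_rate: float = 0.2  # Hz, body-turn rotation rate
    disturbance_step: float = 5e-6  # T, equipment step size (steps model)
    noise_sd: float = 0.15e-6  # per-axis sensor noise SD, T
    dropout: DropoutConfig = field(default_factory=DropoutConfig)
    labeling_noise_sd: float = 0.098  # manual X-ray labeling noise, mm
    amplitude_modulation: bool = False  # free-roaming style envelope
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ConfigError("duration and rate must be > 0")
        for name in ("pp_amplitude", "cycle_jitter", "artifact_amplitude", "noise_sd", "labeling_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        lo, hi = self.depth_range
        if not (0 < lo <= hi):
            raise ConfigError("depth_range must satisfy 0 < lo <= hi")
        if self.disturbance_model not in ("static", "slow-rotation", "steps"):
            raise ConfigError(f"unknown disturbance model {self.disturbance_model!r}")


def speed_to_gait_freq(speed_m_s: float) -> float:
    """Treadmill speed (m/s) to stride rate (Hz): 1.5 Hz at 1.5 m/s, +0.4 Hz per m/s."""
    return 1.5 + 0.4 * (speed_m_s - 1.5)


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Named, independent child stream of the top-level seed."""
    digest = hashlib.sha256(name.encode()).digest()[:8]
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class GroundTruth:
    """Per-frame true bead states and the exact length signal."""

    t: np.ndarray
    p1: np.ndarray  # (n, 3) m
    u1: np.ndarray
    p2: np.ndarray
    u2: np.ndarray
    d: np.ndarray  # (n, 3) T
    length_true: np.ndarray  # mm
    gait_phase: np.ndarray
    toe_strikes: np.ndarray  # sample indices at phase wrap
    rate: float = 155.0
    seed: int = 0

    def __post_init__(self) -> None:
        # length is defined by the positions; assert, don't assume
        check = np.linalg.norm(self.p1 - self.p2, axis=1) * 1e3
        if not np.allclose(check, self.length_true, atol=1e-9):
            raise AssertionError("length_true inconsistent with bead positions")

    def __len__(self) -> int:
        return len(self.t)

    def state(self, i: int) -> PhysicalState:
        return PhysicalState(
            p1=self.p1[i], p2=self.p2[i], u1=self.u1[i], u2=self.u2[i], d=self.d[i]
        )

    def as_length_series(self) -> LengthSeries:
        return LengthSeries(self.t.copy(), self.length_true.copy())


def _gait_phase(n: int, dt: float, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Accumulated phase with per-cycle period jitter (and optional ramp)."""
    t_end = n * dt
    bounds = [0.0]
    freqs = []
    while bounds[-1] < t_end:
        frac = bounds[-1] / t_end
        f = cfg.gait_freq
        if cfg.gait_freq_end is not None:
            f = cfg.gait_freq + (cfg.gait_freq_end - cfg.gait_freq) * frac
        period = (1.0 / f) * (1.0 + cfg.cycle_jitter * rng.standard_normal())
        period = max(period, 0.2 / f)
        freqs.append(1.0 / period)
        bounds.append(bounds[-1] + period)
    t = np.arange(n) * dt
    phase = np.empty(n)
    k = 0
    for i, ti in enumerate(t):
        while k + 1 < len(bounds) - 1 and ti >= bounds[k + 1]:
            k += 1
        phase[i] = k + (ti - bounds[k]) * freqs[k]
    return phase


_W_C2, _W_PSI = 0.35, -0.6


def _waveform(phase: np.ndarray) -> np.ndarray:
    """Two-harmonic stride waveform, normalised to peak-to-peak 2."""
    w = np.cos(2 * np.pi * phase) + _W_C2 * np.cos(4 * np.pi * phase + _W_PSI)
    dense = np.cos(2 * np.pi * np.linspace(0, 1, 4096)) + _W_C2 * np.cos(
        4 * np.pi * np.linspace(0, 1, 4096) + _W_PSI
    )
    lo, hi = dense.min(), dense.max()
    return 2.0 * (w - (lo + hi) / 2.0) / (hi - lo)


def _smooth_drift(
    n: int, dt: float, amplitude: float, max_freq: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited 3-D drift with peak norm ``amplitude`` (same units)."""
    if amplitude == 0:
        return np.zeros((n, 3))
    t = np.arange(n) * dt
    out = np.zeros((n, 3))
    for ax in range(3):
        for _ in range(3):
            f = rng.uniform(0.05, max_freq)
            ph = rng.uniform(0, 2 * np.pi)
            out[:, ax] += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * f * t + ph)
    peak = np.linalg.norm(out, axis=1).max()
    if peak > 0:
        out *= amplitude / peak
    return out


def _rotation_about(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for one axis and many angles; (n, 3, 3)."""
    a = axis / np.linalg.norm(axis)
    Kx = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    s, c = np.sin(angle), np.cos(angle)
    return c[:, None, None] * np.eye(3) + s[:, None, None] * Kx + (1 - c)[:, None, None] * np.outer(a, a)


def _disturbance(n: int, dt: float, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) * dt
    base = rng.standard_normal(3)
    base *= cfg.disturbance_magnitude / np.linalg.norm(base)
    if cfg.disturbance_model == "static":
        return np.tile(base, (n, 1))
    if cfg.disturbance_model == "slow-rotation":
        axis = rng.standard_normal(3)
        R = _rotation_about(axis, 2 * np.pi * cfg.disturbance_rate * t)
        return np.einsum("nij,j->ni", R, base)
    # steps: static ambient plus ±step jumps at Poisson times (nearby equipment)
    d = np.tile(base, (n, 1))
    n_steps = rng.poisson(0.2 * n * dt)
    for _ in range(n_steps):
        i0 = rng.integers(0, n)
        delta = rng.standard_normal(3)
        delta *= cfg.disturbance_step / np.linalg.norm(delta)
        d[i0:] += delta
    return d


def gen_gait_trajectory(cfg: SimConfig) -> GroundTruth:
    """Gait-like bead-pair motion under the array, with soft-tissue artifact.

    The pair is centred under the array, oriented along x, at a midpoint
    depth drawn once per trial from ``depth_range``.  The length signal is
    ``base_length + (pp_amplitude/2) · w(phase)`` with the two-harmonic
    stride waveform ``w`` (peak-to-peak 2); moment directions precess slowly.
    """
    n = int(round(cfg.duration * cfg.rate))
    dt = 1.0 / cfg.rate
    t = np.arange(n) * dt
    phase = _gait_phase(n, dt, cfg, child_rng(cfg.seed, "gait"))
    length = cfg.base_length + 0.5 * cfg.pp_amplitude * _waveform(phase)
    if cfg.amplitude_modulation:
        env = 1.0 + 0.4 * np.sin(
            2 * np.pi * 0.07 * t + child_rng(cfg.seed, "envelope").uniform(0, 2 * np.pi)
        )
        length = cfg.base_length + 0.5 * cfg.pp_amplitude * env * _waveform(phase)

    depth_rng = child_rng(cfg.seed, "depth")
    depth_mm = depth_rng.uniform(*cfg.depth_range)
    artifact = _smooth_drift(
        n, dt, cfg.artifact_amplitude, cfg.artifact_max_freq, child_rng(cfg.seed, "artifact")
    )
    mid = np.column_stack([np.zeros(n), np.zeros(n), np.full(n, depth_mm)]) + artifact
    mid *= 1e-3  # mm -> m
    half = (length / 2.0) * 1e-3
    xhat = np.array([1.0, 0.0, 0.0])
    p1 = mid - half[:, None] * xhat
    p2 = mid + half[:, None] * xhat

    prec = child_rng(cfg.seed, "precession")
    u1_0 = prec.standard_normal(3)
    u1_0 /= np.linalg.norm(u1_0)
    u2_0 = prec.standard_normal(3)
    u2_0 /= np.linalg.norm(u2_0)
    omega = np.deg2rad(cfg.precession_deg_per_cycle) * cfg.gait_freq  # rad/s
    ax1 = prec.standard_normal(3)
    ax2 = prec.standard_normal(3)
    u1 = np.einsum("nij,j->ni", _rotation_about(ax1, omega * t), u1_0)
    u2 = np.einsum("nij,j->ni", _rotation_about(ax2, omega * t), u2_0)

    d = _disturbance(n, dt, cfg, child_rng(cfg.seed, "disturbance"))
    strikes = np.flatnonzero(np.diff(np.floor(phase)) > 0) + 1
    return GroundTruth(
        t=t,
        p1=p1,
        u1=u1,
        p2=p2,
        u2=u2,
        d=d,
        length_true=np.linalg.norm(p1 - p2, axis=1) * 1e3,
        gait_phase=np.mod(phase, 1.0),
        toe_strikes=strikes,
        rate=cfg.rate,
        seed=cfg.seed,
    )


def _dropout_mask(n: int, dt: float, drop: DropoutConfig, rng: np.random.Generator) -> np.ndarray:
    """True where the frame survives; Poisson starts, exponential durations."""
    valid = np.ones(n, dtype=bool)
    if drop.rate <= 0:
        return valid
    t_end = n * dt
    n_events = rng.poisson(drop.rate * t_end)
    starts = np.sort(rng.uniform(0, t_end, n_events))
    durs = rng.exponential(drop.mean_duration, n_events)
    for s, du in zip(starts, durs):
        i0 = int(np.ceil(s / dt))
        i1 = int(np.ceil((s + du) / dt))
        valid[i0 : max(i1, i0 + 1)] = False
    return valid


def sense(
    truth: GroundTruth,
    spec: MagnetSpec | None = None,
    array: SensorArray | None = None,
    cfg: SimConfig | None = None,
) -> FieldStream:
    """Render a ground-truth trajectory into a noisy, droppy sensor stream."""
    spec = spec or MagnetSpec()
    array = array or make_grid_array()
    cfg = cfg or SimConfig(seed=truth.seed)
    n = len(truth)
    fields = np.empty((n, array.n_sensors, 3))
    for i in range(n):
        fields[i] = forward(truth.state(i), spec, array)
    if cfg.noise_sd > 0:
        fields += cfg.noise_sd * child_rng(cfg.seed, "noise").standard_normal(fields.shape)
    valid = _dropout_mask(n, 1.0 / truth.rate, cfg.dropout, child_rng(cfg.seed, "dropout"))
    fields[~valid] = np.nan
    return FieldStream(t=truth.t.copy(), fields=fields, valid=valid, rate=truth.rate)


def gen_reference(
    truth: GroundTruth,
    labeling_noise_sd: float = 0.098,
    offset: float = 0.0,
    drop_windows: list[tuple[float, float]] | None = None,
    seed: int | None = None,
) -> LengthSeries:
    """X-ray-like reference channel: truth plus manual labeling noise.

    Timestamps are shifted by ``offset`` (positive = the reference clock is
    late), i.i.d. Gaussian labeling noise of SD ``labeling_noise_sd`` (mm) is
    added, and samples inside ``drop_windows`` (reference-time intervals) are
    removed, emulating cycles where a marker was obscured.
    """
    if labeling_noise_sd < 0:
        raise ConfigError("labeling_noise_sd must be >= 0")
    rng = child_rng(truth.seed if seed is None else seed, "labeling")
    t = truth.t + offset
    vals = truth.length_true + labeling_noise_sd * rng.standard_normal(len(truth))
    keep = np.ones(len(t), dtype=bool)
    for (a, b) in drop_windows or []:
        keep &= ~((t >= a) & (t <= b))
    return LengthSeries(t[keep], vals[keep], np.full(keep.sum(), GapFlag.MEASURED.value))


def default_benchtop_depths() -> list[float]:
    """Fixture depths in mm: ~1 cm start, 3.2 mm plate increments, 7 levels."""
    return [10.0 + 3.2 * k for k in range(7)]


def benchtop_sweep(
    distance: float = 40.0,
    depth_steps: list[float] | None = None,
    lateral_bound: float = 15.0,
    step: float = 0.5,
    spec: MagnetSpec | None = None,
    array: SensorArray | None = None,
    rate: float = 155.0,
    noise_sd: float = 0.0,
    disturbance: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[FieldStream, GroundTruth]:
    """Rigid fixture sweep: a bead pair at a fixed separation translated
    out-and-back along x then y at each depth.

    ``distance`` (mm) is the fixture separation (default 40 mm),
    ``lateral_bound`` the sweep half-extent (mm), ``step`` the per-frame
    translation (mm).  The true distance is identically ``distance``.
    """
    if distance <= 0:
        raise ConfigError("distance must be > 0")
    depths = depth_steps if depth_steps is not None else default_benchtop_depths()
    leg = np.arange(0.0, lateral_bound + 1e-9, step)
    path_1d = np.concatenate([leg, leg[::-1][1:], -leg[1:], -leg[::-1][1:]])  # out-back both ways
    mids = []
    for z in depths:
        for axis in (0, 1):
            seg = np.zeros((len(path_1d), 3))
            seg[:, axis] = path_1d
            seg[:, 2] = z
            mids.append(seg)
    mid = np.vstack(mids) * 1e-3
    n = len(mid)
    t = np.arange(n) / rate
    half = distance / 2.0 * 1e-3
    xhat = np.array([1.0, 0.0, 0.0])
    p1 = mid - half * xhat
    p2 = mid + half * xhat
    u = np.tile(np.array([0.0, 0.0, 1.0]), (n, 1))  # beads magnetised through-plate
    d = np.tile(np.zeros(3) if disturbance is None else np.asarray(disturbance, float), (n, 1))
    truth = GroundTruth(
        t=t,
        p1=p1,
        u1=u,
        p2=p2,
        u2=u.copy(),
        d=d,
        length_true=np.full(n, float(distance)),
        gait_phase=np.zeros(n),
        toe_strikes=np.array([], dtype=int),
        rate=rate,
        seed=seed,
    )
    cfg = SimConfig(
        duration=max(n / rate, 1e-6),
        rate=rate,
        noise_sd=noise_sd,
        dropout=DropoutConfig(rate=0.0),
        seed=seed,
    )
    stream = sense(truth, spec, array, cfg)
    return stream, truth
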