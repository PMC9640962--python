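"""Forward model: point-dipole fields of two beads plus a uniform disturbance.

The field of a point dipole with moment m (A·m²) at displacement
r = sensor − magnet is

    B(r) = (μ0 / 4π) · (3 (m·r̂) r̂ − m) / |r|³ ,

exact for a uniformly magnetised sphere everywhere outside the sphere.
A spatially uniform disturbance vector d (ambient field: Earth, distant
equipment) is added to every sensor and estimated jointly with the beads.

The solver parameterises the 13-dimensional state as
``[p1 (3), θ1, φ1, p2 (3), θ2, φ2, d (3)]`` where each moment direction is
the unit vector ``u = (sinθ cosφ, sinθ sinφ, cosθ)``; the moment magnitude
is fixed by the magnet specification.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import SingularityError
from .geometry import MagnetSpec, SensorArray

#: μ0 / 4π
K_DIPOLE = 1e-7

#: number of free parameters: two positions, two 2-angle directions, one d
N_PARAMS = 13

_MIN_R = 1e-9  # meters; below this a sensor sits "on" the bead


@dataclass
class PhysicalState:
    """Two bead positions/moment directions plus the uniform disturbance.

    Positions in meters (array frame, +z into tissue), ``u1``/``u2`` unit
    vectors, ``d`` in tesla.
    """

    p1: np.ndarray
    p2: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    d: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "u1", "u2", "d"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))

    def validate(self, require_positive_depth: bool = True) -> None:
        for u, name in ((self.u1, "u1"), (self.u2, "u2")):
            if abs(np.linalg.norm(u) - 1.0) > 1e-9:
                raise ValueError(f"|{name}| must be 1 within 1e-9, got {np.linalg.norm(u)!r}")
        if require_positive_depth and (self.p1[2] <= 0 or self.p2[2] <= 0):
            raise ValueError("bead depths (p1.z, p2.z) must be > 0")

    def separation_mm(self) -> float:
        return float(np.linalg.norm(self.p1 - self.p2) * 1e3)

    def copy(self) -> "PhysicalState":
        return replace(
            self,
            p1=self.p1.copy(),
            p2=self.p2.copy(),
            u1=self.u1.copy(),
            u2=self.u2.copy(),
            d=self.d.copy(),
        )


def unit_from_angles(theta: float, phi: float) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), ct])


def angles_from_unit(u: np.ndarray) -> tuple[float, float]:
    u = np.asarray(u, dtype=float)
    theta = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
    phi = float(np.arctan2(u[1], u[0]))
    return theta, phi


def pack_state(state: PhysicalState) -> np.ndarray:
    t1, f1 = angles_from_unit(state.u1)
    t2, f2 = angles_from_unit(state.u2)
    return np.concatenate([state.p1, [t1, f1], state.p2, [t2, f2], state.d])


def unpack_state(x: np.ndarray) -> PhysicalState:
    x = np.asarray(x, dtype=float)
    return PhysicalState(
        p1=x[0:3],
        u1=unit_from_angles(x[3], x[4]),
        p2=x[5:8],
        u2=unit_from_angles(x[8], x[9]),
        d=x[10:13],
    )


def dipole_field(sensor_pos: np.ndarray, magnet_pos: np.ndarray, moment: np.ndarray) -> np.ndarray:
    """Field (tesla) of a point dipole at one or many sensor positions.

    ``sensor_pos`` may be shape (3,) or (n, 3); the result matches.
    Raises :class:`SingularityError` if any sensor coincides with the bead.
    """
    s = np.asarray(sensor_pos, dtype=float)
    single = s.ndim == 1
    s = np.atleast_2d(s)
    r = s - np.asarray(magnet_pos, dtype=float)
    n2 = np.einsum("ij,ij->i", r, r)
    if np.any(n2 < _MIN_R**2):
        raise SingularityError("sensor position coincides with the magnet position")
    n = np.sqrt(n2)
    m = np.asarray(moment, dtype=float)
    mr = r @ m
    B = K_DIPOLE * (3.0 * mr[:, None] * r / n[:, None] ** 5 - m / n[:, None] ** 3)
    return B[0] if single else B


def dipole_design_matrix(sensor_pos: np.ndarray, magnet_pos: np.ndarray) -> np.ndarray:
    """Matrix A with B = A @ m for a dipole at ``magnet_pos``; shape (n, 3, 3).

    The field is linear in the moment vector, which the cold-start search
    exploits to score candidate positions by a linear least-squares solve.
    """
    s = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    r = s - np.asarray(magnet_pos, dtype=float)
    n2 = np.einsum("ij,ij->i", r, r)
    if np.any(n2 < _MIN_R**2):
        raise SingularityError("sensor position coincides with the magnet position")
    n5 = n2**2.5
    n3 = n2**1.5
    A = 3.0 * r[:, :, None] * r[:, None, :] / n5[:, None, None]
    A -= np.eye(3) / n3[:, None, None]
    return K_DIPOLE * A


def forward(state: PhysicalState, spec: MagnetSpec, array: SensorArray) -> np.ndarray:
    """Predicted per-sensor readings, shape (n_sensors, 3), tesla.

    Sum of the two bead dipole fields plus the uniform disturbance, rotated
    into each sensor's output frame by the array's axis map.
    """
    m = spec.moment_magnitude
    B = dipole_field(array.positions, state.p1, m * state.u1)
    B = B + dipole_field(array.positions, state.p2, m * state.u2)
    B = B + state.d
    if array.identity_axes:
        return B
    return np.einsum("nij,nj->ni", array.axis_map, B)


def dipole_position_jacobian(sensors: np.ndarray, p: np.ndarray, m: np.ndarray) -> np.ndarray:
    """∂B/∂p for one dipole, shape (n, 3, 3).

    From ∂B/∂r = 3k n⁻⁵ [ r mᵀ + m rᵀ + (m·r) I − 5 (m·r) r rᵀ / n² ]
    with r = sensor − p, so ∂B/∂p = −∂B/∂r.
    """
    r = sensors - p
    n2 = np.einsum("ij,ij->i", r, r)
    mr = r @ m
    dBdr = (
        r[:, :, None] * m[None, None, :]
        + m[None, :, None] * r[:, None, :]
        + mr[:, None, None] * np.eye(3)
        - 5.0 * mr[:, None, None] * r[:, :, None] * r[:, None, :] / n2[:, None, None]
    )
    dBdr *= 3.0 * K_DIPOLE / n2[:, None, None] ** 2.5
    return -dBdr


def sph_tangents(theta: float, phi: float) -> tuple[np.ndarray, np.ndarray]:
    """(∂u/∂θ, ∂u/∂φ) of the spherical chart u(θ, φ)."""
    st, ct = np.sin(theta), np.cos(theta)
    sp, cp = np.sin(phi), np.cos(phi)
    return (
        np.array([ct * cp, ct * sp, -st]),
        np.array([-st * sp, st * cp, 0.0]),
    )


def jacobian(state: PhysicalState, spec: MagnetSpec, array: SensorArray) -> np.ndarray:
    """Analytic Jacobian of :func:`forward`, shape (3·n_sensors, 13).

    Rows are sensor-major (sensor 0 x/y/z, sensor 1 x/y/z, ...); columns
    follow the packed parameter order ``[p1, θ1, φ1, p2, θ2, φ2, d]``.
    Note the spherical chart is singular at the poles (∂u/∂φ → 0 as
    sinθ → 0); the tracker avoids this by re-centring the chart on the
    warm-start direction before each solve.
    """
    sensors = array.positions
    n = sensors.shape[0]
    m_mag = spec.moment_magnitude
    J = np.zeros((n, 3, N_PARAMS))
    for bead, (p, u) in enumerate(((state.p1, state.u1), (state.p2, state.u2))):
        theta, phi = angles_from_unit(u)
        dudth, dudph = sph_tangents(theta, phi)
        dBdm = dipole_design_matrix(sensors, p)
        c = 5 * bead
        J[:, :, c : c + 3] = dipole_position_jacobian(sensors, p, m_mag * u)
        J[:, :, c + 3] = dBdm @ (m_mag * dudth)
        J[:, :, c + 4] = dBdm @ (m_mag * dudph)
    J[:, :, 10:13] = np.eye(3)  # disturbance enters linearly
    if not array.identity_axes:
        J = np.einsum("nij,njk->nik", array.axis_map, J)
    return J.reshape(3 * n, N_PARAMS)
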