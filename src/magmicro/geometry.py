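"""Sensor-array geometry and magnet specification.

Coordinate convention: the array frame has its origin at the grid centre,
x along the long (12-sensor) edge, y along the short (8-sensor) edge, and
+z pointing from the array plane into the tissue, so bead depth is a
positive z in meters.  All quantities are SI internally (meters, tesla,
A·m²); file readers convert at the boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError

#: vacuum permeability, T·m/A
MU0 = 4e-7 * np.pi


@dataclass(frozen=True)
class MagnetSpec:
    """A spherical permanent-magnet bead.

    The external field of a uniformly magnetised sphere is exactly the field
    of a point dipole at its centre, so a dipole model is exact here (not an
    approximation) as long as sensors stay outside the bead.

    Parameters
    ----------
    diameter : float
        Bead diameter in meters (default 3 mm).
    remanence : float
        Residual flux density Br in tesla.  N48-class NdFeB sits near 1.4 T.
    """

    diameter: float = 3e-3
    remanence: float = 1.40

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ConfigError(f"magnet diameter must be > 0, got {self.diameter}")
        if self.remanence < 0:
            raise ConfigError(f"remanence must be >= 0, got {self.remanence}")

    @property
    def moment_magnitude(self) -> float:
        """Dipole moment |m| = Br · (π d³ / 6) / μ0, in A·m²."""
        return moment_from_sphere(self)


def moment_from_sphere(spec: MagnetSpec) -> float:
    """Dipole moment magnitude of a uniformly magnetised sphere (A·m²)."""
    volume = np.pi * spec.diameter**3 / 6.0
    return spec.remanence * volume / MU0


@dataclass(frozen=True)
class SensorArray:
    """A rigid set of 3-axis magnetometers in the array frame.

    ``positions`` holds one 3-vector per sensor (meters).  ``axis_map`` holds
    one rotation per sensor taking an array-frame field vector into that
    sensor's output frame; identity for a perfectly assembled board.
    ``rows``/``cols``/``pitch`` are grid metadata present when the array was
    built by :func:`make_grid_array`.
    """

    positions: np.ndarray
    axis_map: np.ndarray = field(default=None)  # type: ignore[assignment]
    rows: int | None = None
    cols: int | None = None
    pitch: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ConfigError(f"positions must be (n, 3), got {pos.shape}")
        object.__setattr__(self, "positions", pos)
        if self.axis_map is None:
            amap = np.broadcast_to(np.eye(3), (pos.shape[0], 3, 3)).copy()
        else:
            amap = np.asarray(self.axis_map, dtype=float)
        if amap.shape != (pos.shape[0], 3, 3):
            raise ConfigError(f"axis_map must be (n, 3, 3), got {amap.shape}")
        # orthonormality check: R Rᵀ = I for every sensor
        err = np.abs(amap @ amap.transpose(0, 2, 1) - np.eye(3)).max()
        if err > 1e-9:
            raise ConfigError(f"axis_map entries are not orthonormal (max |RRᵀ−I| = {err:.2e})")
        object.__setattr__(self, "axis_map", amap)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @property
    def identity_axes(self) -> bool:
        return bool(np.all(self.axis_map == np.eye(3)))

    def span(self) -> tuple[float, float]:
        """(x span, y span) of the sensor footprint in meters."""
        lo = self.positions.min(axis=0)
        hi = self.positions.max(axis=0)
        return float(hi[0] - lo[0]), float(hi[1] - lo[1])

    def subset(self, mask: np.ndarray) -> "SensorArray":
        """Array restricted to the sensors where ``mask`` is True."""
        return SensorArray(
            positions=self.positions[mask],
            axis_map=self.axis_map[mask],
            pitch=self.pitch,
        )


def make_grid_array(rows: int = 8, cols: int = 12, pitch: float = 5.08e-3) -> SensorArray:
    """Planar rows×cols magnetometer grid at z = 0, centred on the origin.

    The default is the 96-sensor wearable board: 8 rows by 12 columns at
    5.08 mm pitch, spanning 35.56 mm × 55.88 mm.
    """
    if rows < 1 or cols < 1:
        raise ConfigError("rows and cols must be >= 1")
    if pitch <= 0:
        raise ConfigError("pitch must be > 0")
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    x = (jj.ravel() - (cols - 1) / 2.0) * pitch
    y = (ii.ravel() - (rows - 1) / 2.0) * pitch
    pos = np.column_stack([x, y, np.zeros_like(x)])
    return SensorArray(positions=pos, rows=rows, cols=cols, pitch=pitch)
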