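"""In-memory containers for sensor frames and length signals."""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import StreamFormatError

#: nominal wireless sampling rate of the sensing array, Hz
NOMINAL_RATE = 155.0


class GapFlag(str, Enum):
    """Per-sample provenance of a length series.

    measured     — solved directly from a sensor frame
    interpolated — filled across a short dropout (< the 50 ms gap threshold)
    gap          — inside a long dropout; no value reported
    """

    MEASURED = "M"
    INTERPOLATED = "I"
    GAP = "G"


@dataclass
class FieldFrame:
    """One timestamped reading of the whole array.

    ``fields`` is (n_sensors, 3) tesla; ``valid`` is False for frames lost to
    packet drops (fields then carry NaN).
    """

    t: float
    fields: np.ndarray | None
    valid: bool = True


@dataclass
class FieldStream:
    """A time-ordered sequence of array frames with a validity mask."""

    t: np.ndarray
    fields: np.ndarray
    valid: np.ndarray
    rate: float = NOMINAL_RATE

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.fields.ndim != 3 or self.fields.shape[2] != 3:
            raise StreamFormatError(f"fields must be (frames, sensors, 3), got {self.fields.shape}")
        if not (len(self.t) == len(self.fields) == len(self.valid)):
            raise StreamFormatError("t, fields and valid must have equal length")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise StreamFormatError(f"timestamps must be strictly increasing (row {i})")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_sensors(self) -> int:
        return self.fields.shape[1]

    def frame(self, i: int) -> FieldFrame:
        return FieldFrame(
            t=float(self.t[i]),
            fields=self.fields[i] if self.valid[i] else None,
            valid=bool(self.valid[i]),
        )

    def with_offset(self, delta: np.ndarray) -> "FieldStream":
        """New stream with a constant 3-vector added to every sensor reading."""
        return FieldStream(
            t=self.t.copy(),
            fields=self.fields + np.asarray(delta, dtype=float),
            valid=self.valid.copy(),
            rate=self.rate,
        )


@dataclass
class LengthSeries:
    """Timestamped inter-bead distances in millimeters with gap annotations."""

    t: np.ndarray
    length_mm: np.ndarray
    flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        if self.flags is None:
            self.flags = np.full(len(self.t), GapFlag.MEASURED.value, dtype="<U1")
        else:
            self.flags = np.asarray(self.flags, dtype="<U1")
        if not (len(self.t) == len(self.length_mm) == len(self.flags)):
            raise StreamFormatError("t, length_mm and flags must have equal length")
        bad = set(np.unique(self.flags)) - {f.value for f in GapFlag}
        if bad:
            raise StreamFormatError(f"unknown gap flags: {sorted(bad)}")
        if len(self.t) > 1 and np.any(np.diff(self.t) <= 0):
            i = int(np.argmax(np.diff(self.t) <= 0)) + 1
            raise StreamFormatError(f"timestamps must be strictly increasing (row {i})")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def has_value(self) -> np.ndarray:
        """Samples carrying a usable value (measured or interpolated)."""
        return self.flags != GapFlag.GAP.value

    @property
    def measured(self) -> np.ndarray:
        return self.flags == GapFlag.MEASURED.value

    def shifted(self, delta_t: float) -> "LengthSeries":
        """Copy with all timestamps shifted by ``delta_t`` seconds."""
        return LengthSeries(self.t + delta_t, self.length_mm.copy(), self.flags.copy())

    def dropna(self) -> "LengthSeries":
        keep = self.has_value & np.isfinite(self.length_mm)
        return LengthSeries(self.t[keep], self.length_mm[keep], self.flags[keep])
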