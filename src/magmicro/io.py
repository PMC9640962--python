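"""File formats: field-stream CSV/HDF5, length-series CSV, run configuration.

Units policy: files declare their field unit (tesla, microtesla, gauss, or a
raw LSB scale) and everything is converted to tesla on read.  Timestamps are
seconds written with enough digits that the 155 Hz spacing round-trips.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, StreamFormatError
from .geometry import MagnetSpec, SensorArray, make_grid_array
from .simulate import DropoutConfig, SimConfig
from .streams import FieldStream, GapFlag, LengthSeries
from .tracker import TrackerConfig

#: multiplicative factors taking declared units to tesla
UNIT_SCALES = {"T": 1.0, "uT": 1e-6, "gauss": 1e-4, "mT": 1e-3, "nT": 1e-9}


def _unit_scale(units: str | float) -> float:
    if isinstance(units, (int, float)):
        if units <= 0:
            raise StreamFormatError("raw LSB scale must be a positive tesla/LSB factor")
        return float(units)
    try:
        return UNIT_SCALES[units]
    except KeyError:
        raise StreamFormatError(
            f"unknown field unit {units!r}; expected one of {sorted(UNIT_SCALES)} or a numeric scale"
        ) from None


def _sensor_columns(n: int) -> list[str]:
    return [f"s{i:03d}_{ax}" for i in range(n) for ax in "xyz"]


def write_field_stream(stream: FieldStream, path: str | Path, units: str | float = "T") -> None:
    """Write a stream as CSV (header ``t_s, s000_x..sNNN_z, valid``) or HDF5.

    The format is chosen by extension (.h5/.hdf5 → HDF5 with datasets
    ``/t``, ``/fields``, ``/valid``).  Invalid frames keep their timestamps
    with empty field cells.
    """
    path = Path(path)
    scale = _unit_scale(units)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("t", data=stream.t)
            f.create_dataset("fields", data=stream.fields / scale)
            f.create_dataset("valid", data=stream.valid)
            f.attrs["units"] = units if isinstance(units, str) else "raw"
            f.attrs["scale_to_T"] = scale
            f.attrs["rate_hz"] = stream.rate
        return
    n = stream.n_sensors
    flat = stream.fields.reshape(len(stream), 3 * n) / scale
    df = pd.DataFrame(flat, columns=_sensor_columns(n))
    df.insert(0, "t_s", stream.t)
    df["valid"] = stream.valid.astype(int)
    df.loc[~stream.valid, _sensor_columns(n)] = np.nan
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_field_stream(
    path: str | Path, units: str | float = "T", rate: float = 155.0
) -> FieldStream:
    """Read a field stream; converts declared units to tesla and enforces
    strictly increasing timestamps (the error names the first bad row)."""
    path = Path(path)
    scale = _unit_scale(units)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            t = f["t"][:]
            fields = f["fields"][:] * scale
            valid = f["valid"][:].astype(bool)
            rate = float(f.attrs.get("rate_hz", rate))
        return FieldStream(t=t, fields=fields, valid=valid, rate=rate)
    df = pd.read_csv(path, float_precision="round_trip")
    if "t_s" not in df.columns:
        raise StreamFormatError(f"{path}: missing required column 't_s'")
    n3 = len([c for c in df.columns if c not in ("t_s", "valid")])
    if n3 % 3:
        raise StreamFormatError(f"{path}: sensor columns not a multiple of 3")
    n = n3 // 3
    cols = _sensor_columns(n)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise StreamFormatError(f"{path}: malformed header, missing {missing[:3]}...")
    t = df["t_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise StreamFormatError(f"{path}: non-monotone timestamp at row {int(bad[0]) + 2}")
    valid = (
        df["valid"].to_numpy(dtype=int).astype(bool)
        if "valid" in df.columns
        else np.ones(len(df), dtype=bool)
    )
    fields = df[cols].to_numpy(dtype=float).reshape(len(df), n, 3) * scale
    return FieldStream(t=t, fields=fields, valid=valid, rate=rate)


def write_length_series(series: LengthSeries, path: str | Path) -> None:
    """CSV with columns ``t_s, length_mm, flag`` (flag ∈ {M, I, G}); gap rows
    carry an empty length field."""
    df = pd.DataFrame(
        {
            "t_s": series.t,
            "length_mm": np.where(series.has_value, series.length_mm, np.nan),
            "flag": series.flags,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")


def read_length_series(path: str | Path) -> LengthSeries:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    for col in ("t_s", "length_mm", "flag"):
        if col not in df.columns:
            raise StreamFormatError(f"{path}: missing required column {col!r}")
    flags = df["flag"].astype(str).to_numpy()
    bad = set(flags) - {f.value for f in GapFlag}
    if bad:
        raise StreamFormatError(f"{path}: unknown flag characters {sorted(bad)}")
    return LengthSeries(
        t=df["t_s"].to_numpy(dtype=float),
        length_mm=df["length_mm"].to_numpy(dtype=float),
        flags=flags,
    )


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Validated end-to-end run settings (array, magnet, sim, solver, alignment)."""

    seed: int = 1
    array: SensorArray = field(default_factory=make_grid_array)
    magnet: MagnetSpec = field(default_factory=MagnetSpec)
    sim: SimConfig = field(default_factory=SimConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    reference_offset: float = 0.0
    alignment_window: float = 0.5
    alignment_global: bool = False
    log_level: str = "info"
    outputs: dict = field(default_factory=dict)


_SCHEMA: dict = {
    "seed": int,
    "log_level": str,
    "array": {"rows": int, "cols": int, "pitch_mm": float},
    "magnet": {"diameter_mm": float, "remanence_T": float},
    "sim": {
        "duration_s": float,
        "rate_hz": float,
        "base_length_mm": float,
        "pp_amplitude_mm": float,
        "gait_freq_hz": float,
        "gait_freq_end_hz": float,
        "depth_range_mm": list,
        "artifact_amplitude_mm": float,
        "precession_deg_per_cycle": float,
        "disturbance": str,
        "disturbance_uT": float,
        "noise_sd_uT": float,
        "dropout_rate_per_s": float,
        "dropout_mean_s": float,
        "labeling_noise_sd_mm": float,
        "reference_offset_s": float,
        "amplitude_modulation": bool,
    },
    "solver": {
        "gtol": float,
        "xtol": float,
        "ftol": float,
        "max_iter_warm": int,
        "max_iter_cold": int,
        "gap_threshold_ms": float,
        "reinit_after_ms": float,
        "full_scale_uT": float,
    },
    "alignment": {"window_s": float, "global": bool},
    "outputs": {"frames": str, "truth": str, "lengths": str, "reference": str, "report": str},
}


def _check_keys(data: dict, schema: dict, prefix: str = "") -> None:
    for key, val in data.items():
        if key not in schema:
            raise ConfigError(f"unknown config key {prefix + key!r}")
        sub = schema[key]
        if isinstance(sub, dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {prefix + key!r} must be a mapping")
            _check_keys(val, sub, prefix + key + ".")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected outright so typos fail loudly rather than
    silently falling back to defaults.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(data, _SCHEMA)
    arr = data.get("array", {})
    array = make_grid_array(
        rows=arr.get("rows", 8),
        cols=arr.get("cols", 12),
        pitch=arr.get("pitch_mm", 5.08) * 1e-3,
    )
    mag = data.get("magnet", {})
    magnet = MagnetSpec(
        diameter=mag.get("diameter_mm", 3.0) * 1e-3,
        remanence=mag.get("remanence_T", 1.40),
    )
    seed = int(data.get("seed", 1))
    s = data.get("sim", {})
    sim = SimConfig(
        duration=s.get("duration_s", 10.0),
        rate=s.get("rate_hz", 155.0),
        base_length=s.get("base_length_mm", 35.0),
        pp_amplitude=s.get("pp_amplitude_mm", 4.5),
        gait_freq=s.get("gait_freq_hz", 1.9),
        gait_freq_end=s.get("gait_freq_end_hz"),
        depth_range=tuple(s.get("depth_range_mm", (11.2, 26.6))),
        artifact_amplitude=s.get("artifact_amplitude_mm", 2.0),
        precession_deg_per_cycle=s.get("precession_deg_per_cycle", 3.0),
        disturbance_model=s.get("disturbance", "slow-rotation"),
        disturbance_magnitude=s.get("disturbance_uT", 50.0) * 1e-6,
        noise_sd=s.get("noise_sd_uT", 0.15) * 1e-6,
        dropout=DropoutConfig(
            rate=s.get("dropout_rate_per_s", 0.2),
            mean_duration=s.get("dropout_mean_s", 0.020),
        ),
        labeling_noise_sd=s.get("labeling_noise_sd_mm", 0.098),
        amplitude_modulation=s.get("amplitude_modulation", False),
        seed=seed,
    )
    sv = data.get("solver", {})
    full_scale = sv.get("full_scale_uT")
    tracker = TrackerConfig(
        gtol=sv.get("gtol", TrackerConfig.gtol),
        xtol=sv.get("xtol", TrackerConfig.xtol),
        ftol=sv.get("ftol", TrackerConfig.ftol),
        max_iter_warm=sv.get("max_iter_warm", TrackerConfig.max_iter_warm),
        max_iter_cold=sv.get("max_iter_cold", TrackerConfig.max_iter_cold),
        gap_threshold=sv.get("gap_threshold_ms", 50.0) * 1e-3,
        reinit_after=sv.get("reinit_after_ms", 250.0) * 1e-3,
        full_scale=None if full_scale is None else full_scale * 1e-6,
    )
    al = data.get("alignment", {})
    return RunConfig(
        seed=seed,
        array=array,
        magnet=magnet,
        sim=sim,
        tracker=tracker,
        reference_offset=s.get("reference_offset_s", 0.0),
        alignment_window=al.get("window_s", 0.5),
        alignment_global=al.get("global", False),
        log_level=data.get("log_level", "info"),
        outputs=data.get("outputs", {}),
    )


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def provenance_block(seed: int, inputs: dict[str, str | Path] | None = None) -> dict:
    from . import __version__

    block = {"package": "magmicro", "version": __version__, "seed": seed}
    if inputs:
        block["input_sha256"] = {k: sha256_of(v) for k, v in inputs.items() if Path(v).exists()}
    return block
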