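"""Sweep containers, run configuration and delimited-text I/O.

Units are fixed throughout the package: angular frequency in rad/s, moduli in
Pa, viscosity in Pa·s, temperature in °C, molar mass in g/mol, time in s.
Numeric tables are plain CSV with one header row and "." decimals; per-file
metadata (temperature, test mode, amplitude, gap, sample id) lives in a JSON
sidecar ``<name>.meta.json`` so the table itself stays trivially parseable.
Frequencies declared in Hz by the sidecar are converted on read (ω = 2πf) and
the conversion is logged.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SweepMode",
    "ValidationError",
    "FrequencySweep",
    "AmplitudeSweep",
    "TemperatureSweep",
    "RelaxationCurve",
    "RunConfig",
    "read_sweep",
    "write_result",
    "read_result",
]


class SweepMode(str, enum.Enum):
    """Test modality: controlled stress (amplitude in Pa) or controlled
    deformation (amplitude is a dimensionless strain)."""

    CS = "CS"
    CD = "CD"


class ValidationError(ValueError):
    """Raised when a file or container violates the domain invariants."""


def _as_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


def _check_lengths(min_len: int, **arrays: np.ndarray) -> None:
    lengths = {k: len(v) for k, v in arrays.items()}
    if len(set(lengths.values())) != 1:
        raise ValidationError(f"array lengths differ: {lengths}")
    n = next(iter(lengths.values()))
    if n < min_len:
        raise ValidationError(f"need at least {min_len} rows, got {n}")


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"non-finite value in column '{name}' at row {bad}")


def _check_nonneg(name: str, arr: np.ndarray) -> None:
    _check_finite(name, arr)
    if np.any(arr < 0):
        bad = int(np.flatnonzero(arr < 0)[0])
        raise ValidationError(f"negative value in column '{name}' at row {bad}")


def _check_positive(name: str, arr: np.ndarray) -> None:
    _check_finite(name, arr)
    if np.any(arr <= 0):
        bad = int(np.flatnonzero(arr <= 0)[0])
        raise ValidationError(f"non-positive value in column '{name}' at row {bad}")


def _check_increasing(name: str, arr: np.ndarray) -> None:
    if np.any(np.diff(arr) <= 0):
        raise ValidationError(f"column '{name}' must be strictly increasing")


@dataclass
class FrequencySweep:
    """G′(ω), G″(ω) measured at one temperature.

    The raw unit of every downstream computation.
    """

    temperature: float
    omega: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    mode: SweepMode = SweepMode.CS
    amplitude: float = 1.0
    gap: float = 1.0
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.omega = _as_array(self.omega, "omega")
        self.g_prime = _as_array(self.g_prime, "g_prime")
        self.g_double_prime = _as_array(self.g_double_prime, "g_double_prime")
        self.mode = SweepMode(self.mode)
        if not math.isfinite(self.temperature):
            raise ValidationError("temperature must be finite")
        _check_lengths(3, omega=self.omega, g_prime=self.g_prime,
                       g_double_prime=self.g_double_prime)
        _check_positive("omega", self.omega)
        _check_increasing("omega", self.omega)
        _check_nonneg("g_prime", self.g_prime)
        _check_nonneg("g_double_prime", self.g_double_prime)

    def __len__(self) -> int:
        return len(self.omega)


@dataclass
class AmplitudeSweep:
    """Moduli versus oscillation amplitude at fixed frequency and temperature."""

    temperature: float
    fixed_omega: float
    amplitude: np.ndarray
    g_prime: np.ndarray
    g_double_prime: np.ndarray
    mode: SweepMode = SweepMode.CD
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.amplitude = _as_array(self.amplitude, "amplitude")
        self.g_prime = _as_array(self.g_prime, "g_prime")
        self.g_double_prime = _as_array(self.g_double_prime, "g_double_prime")
        self.mode = SweepMode(self.mode)
        _check_lengths(3, amplitude=self.amplitude, g_prime=self.g_prime,
                       g_double_prime=self.g_double_prime)
        _check_positive("amplitude", self.amplitude)
        _check_increasing("amplitude", self.amplitude)
        _check_nonneg("g_prime", self.g_prime)
        _check_nonneg("g_double_prime", self.g_double_prime)

    def __len__(self) -> int:
        return len(self.amplitude)


@dataclass
class TemperatureSweep:
    """Complex viscosity and loss tangent versus temperature at fixed ω."""

    temperature: np.ndarray
    viscosity: np.ndarray
    tan_delta: np.ndarray

    def __post_init__(self) -> None:
        self.temperature = _as_array(self.temperature, "temperature_c")
        self.viscosity = _as_array(self.viscosity, "viscosity_pa_s")
        self.tan_delta = _as_array(self.tan_delta, "tan_delta")
        _check_lengths(3, temperature=self.temperature,
                       viscosity=self.viscosity, tan_delta=self.tan_delta)
        _check_finite("temperature_c", self.temperature)
        _check_increasing("temperature_c", self.temperature)
        _check_positive("viscosity_pa_s", self.viscosity)
        _check_positive("tan_delta", self.tan_delta)

    def __len__(self) -> int:
        return len(self.temperature)


@dataclass
class RelaxationCurve:
    """Stress-relaxation modulus G(t) on a strictly increasing time grid."""

    time: np.ndarray
    modulus: np.ndarray

    def __post_init__(self) -> None:
        self.time = _as_array(self.time, "time_s")
        self.modulus = _as_array(self.modulus, "modulus_pa")
        _check_lengths(1, time=self.time, modulus=self.modulus)
        _check_positive("time_s", self.time)
        _check_increasing("time_s", self.time)
        _check_nonneg("modulus_pa", self.modulus)


@dataclass
class GridSpec:
    """A log-spaced grid: bounds plus points per decade."""

    minimum: float
    maximum: float
    points_per_decade: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.minimum < self.maximum):
            raise ValidationError("grid requires 0 < min < max")
        if self.points_per_decade < 1:
            raise ValidationError("points_per_decade must be >= 1")

    def build(self) -> np.ndarray:
        decades = math.log10(self.maximum / self.minimum)
        n = max(2, int(round(decades * self.points_per_decade)) + 1)
        return np.logspace(math.log10(self.minimum), math.log10(self.maximum), n)


@dataclass
class RunConfig:
    """Pipeline configuration; serialized as a single JSON document."""

    lve_tolerance: float = 0.05
    td_drop_fraction: float = 0.5
    lambda_grid: GridSpec = field(default_factory=lambda: GridSpec(1e-4, 1e4, 10))
    mass_grid: GridSpec = field(default_factory=lambda: GridSpec(5.1e4, 1e9, 10))
    regularization_strengths: tuple = tuple(np.logspace(-6, 2, 13))
    tts_reference_temperature: float | None = None
    tts_vertical_shifts: bool = False
    reptation: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.lve_tolerance < 1):
            raise ValidationError("lve_tolerance must lie in (0, 1)")
        if not (0 < self.td_drop_fraction < 1):
            raise ValidationError("td_drop_fraction must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("lambda_grid", "mass_grid"):
            if key in raw:
                raw[key] = GridSpec(**raw[key])
        if "regularization_strengths" in raw:
            raw["regularization_strengths"] = tuple(raw["regularization_strengths"])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["regularization_strengths"] = list(self.regularization_strengths)
        Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# readers

_COLUMNS = {
    "frequency": ["omega_rad_per_s", "g_prime_pa", "g_double_prime_pa"],
    "amplitude": ["amplitude", "g_prime_pa", "g_double_prime_pa"],
    "temperature": ["temperature_c", "viscosity_pa_s", "tan_delta"],
}


def _sidecar(path: Path) -> dict:
    meta_path = path.with_suffix("").with_suffix("")  # strip .csv
    meta_path = path.parent / (path.stem + ".meta.json")
    if meta_path.exists():
        return json.loads(meta_path.read_text())
    return {}


def _read_table(path: Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    df = df[_COLUMNS[kind]]
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise ValidationError(
                f"{path.name}: non-numeric cell in column '{col}' at row {row}")
        df[col] = coerced
    if len(df) < 3:
        raise ValidationError(f"{path.name}: fewer than 3 data rows")
    return df


def read_sweep(path: str | Path, kind: str):
    """Read a sweep table plus its JSON sidecar into a typed container.

    ``kind`` is one of ``frequency``, ``amplitude``, ``temperature``.  Rows are
    normalized to increasing abscissa; invariant violations raise
    :class:`ValidationError` naming the offending row and column.
    """
    path = Path(path)
    if kind not in _COLUMNS:
        raise ValueError(f"unknown sweep kind '{kind}'")
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_table(path, kind)
    meta = _sidecar(path)

    abscissa = _COLUMNS[kind][0]
    df = df.sort_values(abscissa, kind="mergesort").reset_index(drop=True)

    if kind == "frequency":
        omega = df["omega_rad_per_s"].to_numpy()
        if str(meta.get("frequency_unit", "rad/s")).lower() == "hz":
            omega = 2.0 * math.pi * omega
            logger.info("%s: converted frequency column from Hz (omega = 2*pi*f)",
                        path.name)
        return FrequencySweep(
            temperature=float(meta.get("temperature_c", math.nan)),
            omega=omega,
            g_prime=df["g_prime_pa"].to_numpy(),
            g_double_prime=df["g_double_prime_pa"].to_numpy(),
            mode=SweepMode(meta.get("mode", "CS")),
            amplitude=float(meta.get("amplitude", 1.0)),
            gap=float(meta.get("gap_mm", 1.0)),
            sample_id=str(meta.get("sample_id", path.stem)),
        )
    if kind == "amplitude":
        return AmplitudeSweep(
            temperature=float(meta.get("temperature_c", math.nan)),
            fixed_omega=float(meta.get("fixed_omega_rad_per_s", 1.0)),
            amplitude=df["amplitude"].to_numpy(),
            g_prime=df["g_prime_pa"].to_numpy(),
            g_double_prime=df["g_double_prime_pa"].to_numpy(),
            mode=SweepMode(meta.get("mode", "CD")),
            sample_id=str(meta.get("sample_id", path.stem)),
        )
    return TemperatureSweep(
        temperature=df["temperature_c"].to_numpy(),
        viscosity=df["viscosity_pa_s"].to_numpy(),
        tan_delta=df["tan_delta"].to_numpy(),
    )


def write_sweep(sweep, path: str | Path) -> None:
    """Write a sweep container back to CSV + sidecar (inverse of read_sweep)."""
    path = Path(path)
    if isinstance(sweep, FrequencySweep):
        df = pd.DataFrame({
            "omega_rad_per_s": sweep.omega,
            "g_prime_pa": sweep.g_prime,
            "g_double_prime_pa": sweep.g_double_prime,
        })
        meta = {"temperature_c": sweep.temperature, "mode": sweep.mode.value,
                "amplitude": sweep.amplitude, "gap_mm": sweep.gap,
                "sample_id": sweep.sample_id}
    elif isinstance(sweep, AmplitudeSweep):
        df = pd.DataFrame({
            "amplitude": sweep.amplitude,
            "g_prime_pa": sweep.g_prime,
            "g_double_prime_pa": sweep.g_double_prime,
        })
        meta = {"temperature_c": sweep.temperature,
                "fixed_omega_rad_per_s": sweep.fixed_omega,
                "mode": sweep.mode.value, "sample_id": sweep.sample_id}
    elif isinstance(sweep, TemperatureSweep):
        df = pd.DataFrame({
            "temperature_c": sweep.temperature,
            "viscosity_pa_s": sweep.viscosity,
            "tan_delta": sweep.tan_delta,
        })
        meta = {}
    else:
        raise TypeError(f"cannot write {type(sweep).__name__} as a sweep")
    df.to_csv(path, index=False, float_format="%.17g")
    if meta:
        (path.parent / (path.stem + ".meta.json")).write_text(
            json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# result writers: CSV table + JSON summary, 17-digit floats so that a
# read/write round trip is the identity well past 12 significant digits.

def _require_finite(payload: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(payload)):
        raise ValidationError(f"{what} contains non-finite values; refusing to write")


def write_result(result: Any, path: str | Path) -> Path:
    """Write a result object to ``path`` (CSV for tables, JSON for records).

    Distributions additionally get a ``<stem>.summary.json`` next to the CSV.
    Returns the primary path written.
    """
    from .mwd import MWDistribution, summarize_distribution
    from .spectrum import ContinuousSpectrum
    from .tts import MasterCurve, ShiftFactorSet

    path = Path(path)
    if isinstance(result, MWDistribution):
        _require_finite(result.mass_grid, "mass grid")
        _require_finite(result.w, "w(M)")
        pd.DataFrame({"mass_g_per_mol": result.mass_grid, "w": result.w}).to_csv(
            path, index=False, float_format="%.17g")
        summary = summarize_distribution(result)
        (path.parent / (path.stem + ".summary.json")).write_text(
            json.dumps(summary, indent=2))
        return path
    if isinstance(result, ContinuousSpectrum):
        _require_finite(result.lambda_grid, "lambda grid")
        _require_finite(result.H, "H(lambda)")
        pd.DataFrame({"lambda_s": result.lambda_grid, "H_pa": result.H}).to_csv(
            path, index=False, float_format="%.17g")
        return path
    if isinstance(result, MasterCurve):
        for arr, name in ((result.omega, "omega"), (result.g_prime, "G'"),
                          (result.g_double_prime, "G''")):
            _require_finite(arr, name)
        pd.DataFrame({
            "omega_rad_per_s": result.omega,
            "g_prime_pa": result.g_prime,
            "g_double_prime_pa": result.g_double_prime,
            "source_temperature_c": result.source_temperature_per_point,
        }).to_csv(path, index=False, float_format="%.17g")
        return path
    if isinstance(result, RelaxationCurve):
        _require_finite(result.modulus, "modulus")
        pd.DataFrame({"time_s": result.time, "modulus_pa": result.modulus}).to_csv(
            path, index=False, float_format="%.17g")
        return path
    if isinstance(result, ShiftFactorSet):
        payload = {
            "reference_temperature_c": result.reference_temperature,
            "entries": [
                {"temperature_c": t, "log10_aT": a, "log10_bT": b}
                for t, a, b in result.entries
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path
    if isinstance(result, dict):
        def _default(o):
            if isinstance(o, np.ndarray):
                _require_finite(o, "array payload")
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                if not np.isfinite(o):
                    raise ValidationError("non-finite value in payload")
                return o.item()
            raise TypeError(f"unserializable {type(o)}")
        flat = json.dumps(result, indent=2, default=_default, allow_nan=False)
        path.write_text(flat)
        return path
    raise TypeError(f"no writer registered for {type(result).__name__}")


def read_result(path: str | Path, kind: str):
    """Read back a result written by :func:`write_result`.

    ``kind``: ``distribution``, ``spectrum``, ``master_curve``,
    ``relaxation_curve`` or ``json``.
    """
    from .mwd import MWDistribution
    from .spectrum import ContinuousSpectrum
    from .tts import MasterCurve

    path = Path(path)
    if kind == "distribution":
        df = pd.read_csv(path)
        return MWDistribution(mass_grid=df["mass_g_per_mol"].to_numpy(),
                              w=df["w"].to_numpy())
    if kind == "spectrum":
        df = pd.read_csv(path)
        return ContinuousSpectrum(lambda_grid=df["lambda_s"].to_numpy(),
                                  H=df["H_pa"].to_numpy())
    if kind == "master_curve":
        df = pd.read_csv(path)
        return MasterCurve(
            reference_temperature=math.nan,
            omega=df["omega_rad_per_s"].to_numpy(),
            g_prime=df["g_prime_pa"].to_numpy(),
            g_double_prime=df["g_double_prime_pa"].to_numpy(),
            source_temperature_per_point=df["source_temperature_c"].to_numpy(),
        )
    if kind == "relaxation_curve":
        df = pd.read_csv(path)
        return RelaxationCurve(time=df["time_s"].to_numpy(),
                               modulus=df["modulus_pa"].to_numpy())
    if kind == "json":
        return json.loads(path.read_text())
    raise ValueError(f"unknown result kind '{kind}'")
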