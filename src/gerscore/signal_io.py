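"""Reading, calibrating, validating and writing recordings and reports.

The canonical interchange format is a two-column CSV (``time_s,value_uV``
for accelerometry, ``time_s,ph`` for pH traces) with '.' decimal and an
optional header row.  WAV (PCM or float, single channel) is accepted for
long accelerometer recordings, with the physical calibration supplied
externally since WAV carries no units.

Accelerometer samples are held in microvolts (the sensor's analogue
output scale); pH samples in pH units, validated to [0, 14].
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import (
    EmptyInputError,
    ParseError,
    SamplingError,
    ValidationError,
)

__all__ = [
    "CalibrationSpec",
    "Recording",
    "PhRecording",
    "read_recording",
    "read_ph",
    "write_recording",
    "write_ph",
    "write_report",
]

#: Relative jitter tolerance on CSV timestamps: max |dt - median dt| < 0.1 / fs.
UNIFORMITY_TOLERANCE = 0.1


@dataclass(frozen=True)
class CalibrationSpec:
    """Linear calibration from raw file units to microvolts.

    ``value_uV = raw * volts_per_unit + dc_offset``
    """

    volts_per_unit: float = 1.0
    dc_offset: float = 0.0  # µV, applied after scaling

    def __post_init__(self) -> None:
        if self.volts_per_unit == 0:
            raise ValidationError("CalibrationSpec.volts_per_unit must be non-zero")

    def apply(self, raw: np.ndarray) -> np.ndarray:
        return np.asarray(raw, dtype=np.float64) * self.volts_per_unit + self.dc_offset


@dataclass
class Recording:
    """A uniformly sampled single-channel accelerometer trace in µV."""

    samples: np.ndarray
    fs: float = 200.0
    start_time: Optional[str] = None
    channel_label: str = "accel-z"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValidationError("Recording.samples must be one-dimensional")
        if not self.fs > 0:
            raise ValidationError(f"Recording.fs must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
            raise ValidationError(f"non-finite sample at index {bad}")

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.fs

    def require_nonempty(self) -> None:
        if len(self.samples) == 0:
            raise EmptyInputError("recording has no samples")


@dataclass
class PhRecording:
    """A uniformly sampled esophageal pH trace (pH units in [0, 14])."""

    samples: np.ndarray
    fs: float = 1.0
    start_time: Optional[str] = None
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not self.fs > 0:
            raise ValidationError(f"PhRecording.fs must be positive, got {self.fs}")
        if self.samples.size:
            if not np.all(np.isfinite(self.samples)):
                bad = int(np.flatnonzero(~np.isfinite(self.samples))[0])
                raise ValidationError(f"non-finite pH sample at index {bad}")
            out = (self.samples < 0.0) | (self.samples > 14.0)
            if np.any(out):
                bad = int(np.flatnonzero(out)[0])
                raise ValidationError(
                    f"pH sample {self.samples[bad]:g} at index {bad} outside [0, 14]"
                )

    @property
    def duration_seconds(self) -> float:
        return len(self.samples) / self.fs


def _read_two_column_csv(path: Union[str, Path], value_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-column (time, value) CSV with optional header."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        first = path.open("r", encoding="utf-8").readline()
    except OSError as exc:  # pragma: no cover - OS dependent
        raise ParseError(f"{path}: {exc}") from exc
    if first == "":
        raise EmptyInputError(f"{path}: file is empty")
    header = 0
    try:
        float(first.split(",")[0])
        header = None
    except ValueError:
        pass
    try:
        df = pd.read_csv(path, header=header)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] != 2:
        raise ParseError(f"{path}: expected 2 columns (time_s,{value_name}), got {df.shape[1]}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.index[coerced.isna()][0]
            raise ParseError(f"{path}: non-numeric value at data row {bad}")
    t = df.iloc[:, 0].to_numpy(dtype=np.float64)
    v = df.iloc[:, 1].to_numpy(dtype=np.float64)
    if np.any(~np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v))[0])
        raise ParseError(f"{path}: NaN/Inf value at data row {bad}")
    if np.any(~np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0])
        raise ParseError(f"{path}: NaN/Inf timestamp at data row {bad}")
    return t, v


def _infer_fs(t: np.ndarray, path: Union[str, Path]) -> float:
    """Infer the sampling rate from CSV timestamps, refusing non-uniform data.

    The rate is 1 / median interval; any interval deviating from the median
    by more than 0.1 / fs is rejected rather than silently resampled, and a
    near-integer rate is snapped so round-trips preserve fs exactly.
    """
    if len(t) < 2:
        return 1.0
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingError(f"{path}: non-increasing timestamps")
    tol = UNIFORMITY_TOLERANCE * med
    worst = int(np.argmax(np.abs(dt - med)))
    if abs(dt[worst] - med) >= tol:
        raise SamplingError(
            f"{path}: non-uniform sampling at row {worst + 1}: interval "
            f"{dt[worst]:.6g} s vs median {med:.6g} s (tolerance {tol:.2g} s)"
        )
    fs = 1.0 / med
    if abs(fs - round(fs)) < 1e-6 * fs:
        fs = float(round(fs))
    return fs


def read_recording(
    path: Union[str, Path],
    format: Optional[str] = None,
    calibration: Optional[CalibrationSpec] = None,
    fs_override: Optional[float] = None,
    subject_id: str = "",
) -> Recording:
    """Read an accelerometer recording from CSV or WAV, calibrated to µV.

    Parameters
    ----------
    path
        Input file.  ``format`` defaults from the extension.
    format
        ``"csv"`` (two columns: time_s, value_uV) or ``"wav"`` (mono PCM/float).
    calibration
        Linear scale from raw units to µV; identity by default.
    fs_override
        Force the sampling rate instead of inferring it (CSV) or reading the
        header (WAV).
    """
    path = Path(path)
    cal = calibration or CalibrationSpec()
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        t, v = _read_two_column_csv(path, "value_uV")
        fs = fs_override if fs_override is not None else _infer_fs(t, path)
        return Recording(samples=cal.apply(v), fs=float(fs), subject_id=subject_id)
    if fmt == "wav":
        try:
            rate, data = wavfile.read(path)
        except FileNotFoundError:
            raise ParseError(f"{path}: no such file") from None
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        data = np.asarray(data)
        if data.ndim != 1:
            raise ParseError(f"{path}: expected single-channel WAV, got {data.shape[1]} channels")
        if data.size == 0:
            raise EmptyInputError(f"{path}: zero-length WAV")
        fs = fs_override if fs_override is not None else float(rate)
        return Recording(samples=cal.apply(data), fs=float(fs), subject_id=subject_id)
    raise ParseError(f"unknown recording format {fmt!r} (expected csv or wav)")


def read_ph(
    path: Union[str, Path],
    fs_override: Optional[float] = None,
    subject_id: str = "",
) -> PhRecording:
    """Read an esophageal pH trace from CSV; values validated to [0, 14]."""
    path = Path(path)
    t, v = _read_two_column_csv(path, "ph")
    fs = fs_override if fs_override is not None else _infer_fs(t, path)
    return PhRecording(samples=v, fs=float(fs), subject_id=subject_id)


def write_recording(rec: Recording, path: Union[str, Path]) -> None:
    """Write a Recording as canonical CSV (header ``time_s,value_uV``)."""
    t = np.arange(len(rec.samples)) / rec.fs
    _write_csv_pair(path, "time_s,value_uV", t, rec.samples)


def write_ph(ph: PhRecording, path: Union[str, Path]) -> None:
    """Write a PhRecording as canonical CSV (header ``time_s,ph``)."""
    t = np.arange(len(ph.samples)) / ph.fs
    _write_csv_pair(path, "time_s,ph", t, ph.samples)


def _write_csv_pair(path, header: str, t: np.ndarray, v: np.ndarray) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for ti, vi in zip(t, v):
            fh.write(f"{float(ti)!r},{float(vi)!r}\n")


def _report_to_dict(report) -> dict:
    if dataclasses.is_dataclass(report) and not isinstance(report, type):
        d = dataclasses.asdict(report)
    elif isinstance(report, dict):
        d = dict(report)
    else:
        raise ValidationError(f"cannot serialize report of type {type(report).__name__}")

    def _clean(x):
        if isinstance(x, dict):
            return {k: _clean(v) for k, v in x.items()}
        if isinstance(x, (list, tuple)):
            return [_clean(v) for v in x]
        if isinstance(x, np.generic):
            return x.item()
        if isinstance(x, np.ndarray):
            return x.tolist()
        return x

    return _clean(d)


def write_report(report, path: Union[str, Path], format: str = "json") -> None:
    """Serialize a result object (AccelReport, BoixOchoaResult, ContingencyTable).

    JSON round-trips every scalar field bit-exactly (``repr`` float encoding);
    CSV writes a 2x2 layout for contingency tables and key/value rows otherwise.
    """
    path = Path(path)
    fmt = format.lower()
    d = _report_to_dict(report)
    if fmt == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    if fmt == "csv":
        cells = {"both_pos", "accel_pos_ph_neg", "accel_neg_ph_pos", "both_neg"}
        with path.open("w", encoding="utf-8") as fh:
            if cells <= set(d):
                fh.write(",ph_positive,ph_negative\n")
                fh.write(f"accel_positive,{d['both_pos']},{d['accel_pos_ph_neg']}\n")
                fh.write(f"accel_negative,{d['accel_neg_ph_pos']},{d['both_neg']}\n")
            else:
                fh.write("field,value\n")
                for k, v in d.items():
                    fh.write(f"{k},{json.dumps(v) if isinstance(v, (dict, list)) else v}\n")
        return
    raise ValidationError(f"unknown report format {format!r} (expected json or csv)")


def read_report(path: Union[str, Path]) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with Path(path).open("r", encoding="utf-8") as fh:
        return json.load(fh)
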