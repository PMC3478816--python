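"""Domain types and delimited-text I/O for shank IMU recordings.

A recording holds the three sagittal-plane channels a shank-mounted
inertial unit provides: the specific force along the shank's long axis
(``a_n``, ≈ +g when the shank is vertical and still), the antero-posterior
specific force (``a_t``), and the angular speed about the mediolateral
axis (``omega``).  Files are plain CSV with a ``time`` column in seconds;
metadata travels as ``#key=value`` comment lines before the header.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, FormatError, SamplingError, ValidationError

__all__ = [
    "IMURecording",
    "PipelineConfig",
    "read_recording",
    "write_recording",
    "load_config",
]

#: maximum relative jitter of the time step tolerated by read_recording
MAX_STEP_JITTER = 0.01


@dataclass
class IMURecording:
    """Uniformly sampled shank-frame signals.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing and uniform.
    a_n : ndarray
        Shank-normal specific force, m/s² (along the shank long axis).
    a_t : ndarray
        Shank-tangential (antero-posterior) specific force, m/s².
    omega : ndarray
        Sagittal angular speed about the mediolateral axis, rad/s.
    fs : float
        Sampling frequency, Hz; must match the time column.
    meta : dict
        Free-form labels (subject id, true slope if known, ...).
    """

    time: np.ndarray
    a_n: np.ndarray
    a_t: np.ndarray
    omega: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.a_n = np.asarray(self.a_n, dtype=float)
        self.a_t = np.asarray(self.a_t, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValidationError("recording needs at least 2 samples")
        for name in ("a_n", "a_t", "omega"):
            arr = getattr(self, name)
            if arr.shape != self.time.shape:
                raise ValidationError(
                    f"signal '{name}' length {arr.size} != time length {n}"
                )
        for name in ("time", "a_n", "a_t", "omega"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise DataError(f"non-finite samples in '{name}'")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time column must be strictly increasing")
        if not (self.fs > 0):
            raise ValidationError("fs must be positive")
        if not math.isclose(self.fs, 1.0 / float(np.median(dt)), rel_tol=1e-6):
            raise ValidationError(
                f"fs={self.fs} inconsistent with median time step {np.median(dt)}"
            )

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return float(self.time[-1] - self.time[0])


@dataclass
class PipelineConfig:
    """Tunable parameters of the slope-estimation pipeline.

    Defaults follow the reference processing chain: gravity 9.8 m/s²,
    a 4 Hz zero-phase low-pass for event detection, and a 5-stride
    moving-average kernel for smoothing.
    """

    g: float = 9.8                    #: gravity, m/s²
    cutoff_hz: float = 4.0            #: low-pass cut-off for detection, Hz
    ma_kernel: int = 5                #: moving-average length, strides (odd)
    min_stride_s: float = 0.4         #: minimum stride duration, s
    swing_peak_quantile: float = 0.7  #: swing-peak threshold, fraction of max ω
    epsilon_displacement: float = 0.05  #: |S_ap| below this flags a stride, m
    tilt_window: int = 0              #: ±k-sample median for mid-stance tilt
    use_tilt_correction: bool = True  #: False reproduces the zero-tilt baseline
    omega_in_degrees: bool = False    #: convert gyro channel from deg/s
    flip_omega: bool = False          #: force a frame mirror flip
    auto_flip: bool = True            #: flip automatically if swing lobe is negative

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValidationError("g must be positive")
        if not self.cutoff_hz > 0:
            raise ValidationError("cutoff_hz must be positive")
        k = self.ma_kernel
        if not (isinstance(k, (int, np.integer)) and k > 0 and k % 2 == 1):
            raise ValidationError("ma_kernel must be an odd positive integer")
        if not 0 < self.swing_peak_quantile < 1:
            raise ValidationError("swing_peak_quantile must lie in (0, 1)")

    def validate_for_fs(self, fs: float) -> None:
        if not self.cutoff_hz < fs / 2:
            raise ValidationError(
                f"cutoff_hz={self.cutoff_hz} must be below the Nyquist rate {fs / 2}"
            )


_DEFAULT_COLUMNS = {"time": "time", "a_n": "a_n", "a_t": "a_t", "omega": "omega"}


def read_recording(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> IMURecording:
    """Read a CSV recording written by :func:`write_recording` (or any
    delimited file with compatible columns).

    ``column_map`` maps the canonical names (``time``, ``a_n``, ``a_t``,
    ``omega``) to the column names used in the file.  The sampling rate is
    inferred from the median time step rather than trusted from metadata.
    """
    path = Path(path)
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)

    meta: dict[str, Any] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = _coerce(val.strip())
            else:
                data_lines.append(line)
    try:
        df = pd.read_csv(_io.StringIO("".join(data_lines)))
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc

    missing = [cols[k] for k in ("time", "a_n", "a_t", "omega") if cols[k] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")

    time = df[cols["time"]].to_numpy(dtype=float)
    if time.size < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    for name in ("time", "a_n", "a_t", "omega"):
        vals = df[cols[name]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DataError(f"{path}: non-finite values in column '{cols[name]}'")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise SamplingError(f"{path}: time column not strictly increasing")
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > MAX_STEP_JITTER * med:
        raise SamplingError(
            f"{path}: non-uniform sampling (step jitter exceeds {MAX_STEP_JITTER:.0%})"
        )
    return IMURecording(
        time=time,
        a_n=df[cols["a_n"]].to_numpy(dtype=float),
        a_t=df[cols["a_t"]].to_numpy(dtype=float),
        omega=df[cols["omega"]].to_numpy(dtype=float),
        fs=1.0 / med,
        meta=meta,
    )


def write_recording(rec: IMURecording, path: str | Path) -> Path:
    """Write a recording as CSV: ``#key=value`` metadata comments, then a
    ``time,a_n,a_t,omega`` header and full-precision data rows."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in rec.meta.items():
            fh.write(f"#{key}={val}\n")
        fh.write("time,a_n,a_t,omega\n")
        for row in zip(rec.time, rec.a_n, rec.a_t, rec.omega):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")
    return path


def load_config(path: str | Path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML or JSON file.

    Unknown keys are rejected so typos fail loudly.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _coerce(val: str) -> Any:
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            continue
    return val
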