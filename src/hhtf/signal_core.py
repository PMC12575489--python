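"""Data model, CSV I/O, resampling and filtering primitives.

The package works with paired inertial recordings: a helmet-mounted IMU
(tri-axial accelerometer in g, tri-axial gyroscope in deg/s, 1024 Hz) and a
reference sensor pack at the headform centre of mass (10 kHz).  Everything
downstream — impact detection, direction estimation, the autoregressive
transfer function — consumes the :class:`ImuRecording` container and the
filtering helpers defined here.

Units: time in seconds, linear acceleration in g, angular rate in deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

CSV_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]

#: Hardware defaults for the two sensor packs.
HELMET_RATE_HZ = 1024.0
HEADFORM_RATE_HZ = 10_000.0
WORKING_RATE_HZ = 10_000.0  # helmet signals are upsampled to this before analysis

#: Relative jitter tolerated in the CSV time column before the grid is
#: declared non-uniform.
MAX_TIME_JITTER = 0.01


class FormatError(ValueError):
    """CSV file does not follow the expected layout."""


class DataError(ValueError):
    """Signal values violate a precondition (non-finite, non-uniform grid)."""


@dataclass
class ImuRecording:
    """Uniformly sampled tri-axial accelerometer + gyroscope streams.

    Attributes
    ----------
    time : (N,) array, seconds, strictly uniform grid
    accel : (3, N) array, g
    gyro : (3, N) array, deg/s
    rate : sampling rate, Hz
    frame : 'TF' (sensor technical frame), 'FF' (functional/anatomical
        frame) or 'PCA' (impact-specific principal frame)
    sensor : 'helmet' or 'headform'
    """

    time: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    rate: float
    frame: Literal["TF", "FF", "PCA"] = "TF"
    sensor: Literal["helmet", "headform"] = "helmet"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        n = self.time.size
        if n < 2:
            raise DataError("recording needs at least 2 samples")
        if self.accel.shape != (3, n) or self.gyro.shape != (3, n):
            raise DataError(
                f"accel/gyro must be 3x{n}, got {self.accel.shape} and {self.gyro.shape}"
            )
        if not (np.isfinite(self.time).all() and np.isfinite(self.accel).all()
                and np.isfinite(self.gyro).all()):
            raise DataError("non-finite values in recording")
        dt = np.diff(self.time)
        if dt.min() <= 0:
            raise DataError("time column must be strictly increasing")
        step = 1.0 / self.rate
        if np.abs(dt - step).max() > MAX_TIME_JITTER * step:
            raise DataError("time grid is not uniform at the stated rate")

    @property
    def n_samples(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class FilterSpec:
    """A low-pass filter request.

    ``kind='butterworth_lp'`` is a zero-phase (forward-backward) Butterworth
    with -3 dB per pass at ``cutoff`` Hz.  ``kind='cfc'`` is a channel
    frequency class filter in the crash-test tradition: ``cutoff`` is then
    the class number (e.g. 1000) and the -3 dB point of the two-pass design
    sits at 1.65 x class, per the standard class definition.
    """

    kind: Literal["butterworth_lp", "cfc"] = "butterworth_lp"
    cutoff: float = 200.0
    order: int = 4
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order not in (2, 4):
            raise ValueError("order must be 2 or 4")


def read_recording(path: str | Path, sensor: str = "helmet",
                   frame: str = "TF") -> ImuRecording:
    """Read a ``t,ax,ay,az,gx,gy,gz`` CSV into an :class:`ImuRecording`.

    The sampling rate is inferred from the median time step; jitter beyond
    1% of that step raises :class:`DataError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing columns {missing} in {path}")
    values = df[CSV_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise DataError(f"non-finite values in {path}")
    t = values[:, 0]
    dt = np.diff(t)
    if t.size < 2 or dt.min() <= 0:
        raise DataError(f"time column of {path} is not strictly increasing")
    rate = 1.0 / float(np.median(dt))
    return ImuRecording(time=t, accel=values[:, 1:4].T, gyro=values[:, 4:7].T,
                        rate=rate, frame=frame, sensor=sensor)


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    """Write a recording as the canonical 7-column CSV (full float precision)."""
    df = pd.DataFrame(
        np.column_stack([rec.time, rec.accel.T, rec.gyro.T]), columns=CSV_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.12g")


def resample(rec: ImuRecording, target_rate: float,
             method: Literal["spline", "linear"] = "spline") -> ImuRecording:
    """Upsample all channels onto a uniform grid at ``target_rate``.

    Only upsampling is supported (helmet 1024 Hz -> working 10 kHz); the
    grid spans the same interval and preserves the endpoints.  Cubic-spline
    interpolation is the default — the pulses are band-limited well below
    the helmet Nyquist so splines track them without ringing.
    """
    if target_rate < rec.rate:
        raise ValueError("downsampling is not supported")
    if target_rate == rec.rate:
        return rec
    duration = rec.time[-1] - rec.time[0]
    n_new = int(np.floor(duration * target_rate + 1e-9)) + 1
    t_new = rec.time[0] + np.arange(n_new) / target_rate
    if t_new[-1] > rec.time[-1]:  # float round-up past the original end
        t_new = t_new[:-1]

    def _interp(mat: np.ndarray) -> np.ndarray:
        if method == "spline":
            return CubicSpline(rec.time, mat, axis=1)(t_new)
        return np.vstack([np.interp(t_new, rec.time, row) for row in mat])

    return replace(rec, time=t_new, accel=_interp(rec.accel),
                   gyro=_interp(rec.gyro), rate=float(target_rate))


def _butter_sos(spec: FilterSpec, rate: float) -> np.ndarray:
    if spec.kind == "cfc":
        # class N -> -3 dB of the two-pass filter at 1.65*N Hz; a two-pass
        # 2nd-order Butterworth reaches its combined -3 dB at
        # fc * (sqrt(2)-1)^(1/4), so widen the per-pass design accordingly,
        # in prewarped (bilinear) frequency so the digital response lands there
        f3db = 1.65 * spec.cutoff
        if f3db >= rate / 2:
            raise ValueError(f"CFC {spec.cutoff:g} -3 dB point is beyond Nyquist")
        ratio = (np.sqrt(2.0) - 1.0) ** 0.25
        fc = rate / np.pi * np.arctan(np.tan(np.pi * f3db / rate) / ratio)
        order = 2
    else:
        fc = spec.cutoff
        order = spec.order
    if fc >= rate / 2:
        raise ValueError(f"cutoff {fc:g} Hz is at or above Nyquist ({rate / 2:g} Hz)")
    return sps.butter(order, fc, btype="low", fs=rate, output="sos")


def lowpass_trace(trace: np.ndarray, spec: FilterSpec, rate: float) -> np.ndarray:
    """Zero-phase low-pass of a 1-D trace (or each row of a 2-D array)."""
    trace = np.asarray(trace, dtype=float)
    sos = _butter_sos(spec, rate)
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, trace, axis=-1)
    return sps.sosfilt(sos, trace, axis=-1)


def lowpass(rec: ImuRecording, spec: FilterSpec,
            channels: Literal["accel", "gyro", "both"] = "both") -> ImuRecording:
    """Apply :func:`lowpass_trace` to a recording's channels."""
    accel = lowpass_trace(rec.accel, spec, rec.rate) if channels in ("accel", "both") else rec.accel
    gyro = lowpass_trace(rec.gyro, spec, rec.rate) if channels in ("gyro", "both") else rec.gyro
    return replace(rec, accel=accel, gyro=gyro)


def vector_norm(matrix: np.ndarray) -> np.ndarray:
    """Euclidean norm per sample of a 3xN channel matrix."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] != 3:
        raise ValueError("expected a 3xN matrix")
    return np.linalg.norm(matrix, axis=0)
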