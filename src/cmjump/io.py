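"""Reading, writing and calibrating smartphone-IMU and force-platform signals.

The module turns raw CSV recordings into world-vertical, gravity-free
acceleration traces (:class:`AccelTrace`), the common currency of the rest of
the package.  Two sources exist:

* ``SP`` — a handheld smartphone IMU (triaxial accelerometer in m/s²,
  triaxial gyroscope in deg/s), nominally 128 samples/s, ±8 g full scale.
  Sensor offset/scale errors are corrected from three gravity-aligned static
  acquisitions; the trace is then tilt-corrected so the static-phase mean
  acceleration maps onto the world vertical, and g is subtracted.
* ``FP`` — a force platform measuring the total vertical ground-reaction
  force in N, nominally 1000 samples/s.  Body mass is taken from the first
  static second (mean Fz / g) and the trace converted as a = Fz/m − g.

CSV dialects (column names, delimiter, time unit) are declared in a small
mapping so exports from different apps can be read; the default follows a
Phyphox-style export with columns ``time_s,acc_x,acc_y,acc_z,gyr_x,gyr_y,gyr_z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, FormatError, QualityError

#: standard gravity used everywhere in the package, m/s²
G = 9.81

#: accelerometer full scale, m/s² (±8 g)
ACC_FULL_SCALE = 8.0 * G

DEFAULT_IMU_DIALECT: dict = {
    "time": "time_s",
    "acc": ("acc_x", "acc_y", "acc_z"),
    "gyro": ("gyr_x", "gyr_y", "gyr_z"),
    "time_unit": "s",  # or "ms"
    "delimiter": ",",
}

DEFAULT_FP_DIALECT: dict = {
    "time": "time_s",
    "force": ("fz_n",),  # or ("fz1_n", "fz2_n") summed on read
    "time_unit": "s",
    "delimiter": ",",
}


def _as_seconds(t: np.ndarray, unit: str) -> np.ndarray:
    if unit == "s":
        return t
    if unit == "ms":
        return t / 1000.0
    raise FormatError(f"unknown time unit {unit!r} (expected 's' or 'ms')")


def _check_monotone(t: np.ndarray) -> None:
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise DataError(
            f"time column not strictly increasing at row {i + 1} "
            f"(t={t[i]:.6f} -> {t[i + 1]:.6f})"
        )


def _infer_fs(t: np.ndarray) -> float:
    return 1.0 / float(np.median(np.diff(t)))


@dataclass
class RawImuRecord:
    """Raw triaxial IMU samples in SI units (acc m/s², gyro deg/s)."""

    t: np.ndarray
    acc: np.ndarray  # (n, 3)
    gyro: np.ndarray  # (n, 3)
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        _check_monotone(self.t)
        if not np.all(np.isfinite(self.acc)) or not np.all(np.isfinite(self.gyro)):
            raise DataError("non-finite IMU samples")
        med_dt = float(np.median(np.diff(self.t)))
        if abs(med_dt - 1.0 / self.fs) * self.fs > 0.05:
            raise DataError(
                f"median sample interval {med_dt:.6f}s inconsistent with fs={self.fs}"
            )
        if np.any(np.abs(self.acc) > ACC_FULL_SCALE * 1.01):
            raise DataError("acceleration exceeds the ±8 g full scale")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class RawForceRecord:
    """Vertical ground-reaction force (N), already summed over plates."""

    t: np.ndarray
    fz: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.fz = np.asarray(self.fz, dtype=float)
        _check_monotone(self.t)
        if not np.all(np.isfinite(self.fz)):
            raise DataError("non-finite force samples")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class CalibrationSet:
    """Per-axis accelerometer offset (m/s²) + scale, and gyroscope bias (deg/s)."""

    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def __post_init__(self) -> None:
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
        self.accel_offset = np.asarray(self.accel_offset, dtype=float)
        self.accel_scale = np.asarray(self.accel_scale, dtype=float)
        if not (
            np.all(np.isfinite(self.gyro_bias))
            and np.all(np.isfinite(self.accel_offset))
            and np.all(np.isfinite(self.accel_scale))
        ):
            raise CalibrationError("non-finite calibration values")
        if np.any(self.accel_scale <= 0.5) or np.any(self.accel_scale >= 1.5):
            raise CalibrationError("accelerometer scale outside (0.5, 1.5)")


@dataclass
class AccelTrace:
    """Uniformly sampled world-vertical acceleration, gravity removed, up positive."""

    t: np.ndarray
    a: np.ndarray
    fs: float
    source: str  # "SP" or "FP"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if self.source not in ("SP", "FP"):
            raise DataError(f"unknown trace source {self.source!r}")
        if not np.all(np.isfinite(self.a)):
            raise DataError("non-finite acceleration samples")

    def index_at(self, time: float) -> int:
        """Index of the sample nearest to ``time`` (seconds)."""
        return int(np.argmin(np.abs(self.t - time)))

    def window(self, t_start: float, t_stop: float) -> slice:
        """Slice covering samples with t_start <= t <= t_stop (inclusive)."""
        i0 = int(np.searchsorted(self.t, t_start, side="left"))
        i1 = int(np.searchsorted(self.t, t_stop, side="right"))
        if i0 >= i1:
            raise DataError(f"window [{t_start}, {t_stop}] contains no samples")
        return slice(i0, i1)


# ---------------------------------------------------------------------------
# CSV I/O


def read_imu_csv(path, dialect: Mapping | None = None) -> RawImuRecord:
    """Read a smartphone IMU export.

    The ``dialect`` mapping names the time/acceleration/gyroscope columns,
    the delimiter and the time unit (``"s"`` or ``"ms"``); unset keys fall
    back to the Phyphox-style :data:`DEFAULT_IMU_DIALECT`.  No resampling is
    applied here.
    """
    d = {**DEFAULT_IMU_DIALECT, **(dialect or {})}
    path = Path(path)
    df = pd.read_csv(path, delimiter=d["delimiter"])
    needed = [d["time"], *d["acc"], *d["gyro"]]
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"missing column {col!r} in {path.name}")
    t = _as_seconds(df[d["time"]].to_numpy(dtype=float), d["time_unit"])
    _check_monotone(t)
    acc = df[list(d["acc"])].to_numpy(dtype=float)
    gyro = df[list(d["gyro"])].to_numpy(dtype=float)
    return RawImuRecord(t=t, acc=acc, gyro=gyro, fs=_infer_fs(t))


def write_imu_csv(rec: RawImuRecord, path, dialect: Mapping | None = None) -> None:
    d = {**DEFAULT_IMU_DIALECT, **(dialect or {})}
    t = rec.t * (1000.0 if d["time_unit"] == "ms" else 1.0)
    df = pd.DataFrame({d["time"]: t})
    for j, col in enumerate(d["acc"]):
        df[col] = rec.acc[:, j]
    for j, col in enumerate(d["gyro"]):
        df[col] = rec.gyro[:, j]
    df.to_csv(path, sep=d["delimiter"], index=False)


def read_fp_csv(path, dialect: Mapping | None = None) -> RawForceRecord:
    """Read a force-platform export; multiple force columns are summed."""
    d = {**DEFAULT_FP_DIALECT, **(dialect or {})}
    path = Path(path)
    df = pd.read_csv(path, delimiter=d["delimiter"])
    if d["time"] not in df.columns:
        raise FormatError(f"missing column {d['time']!r} in {path.name}")
    force_cols = d["force"]
    if isinstance(force_cols, str):
        force_cols = (force_cols,)
    present = [c for c in force_cols if c in df.columns]
    if not present:
        # allow the two-plate layout as an automatic fallback
        if {"fz1_n", "fz2_n"} <= set(df.columns):
            present = ["fz1_n", "fz2_n"]
        else:
            raise FormatError(f"missing force column(s) {force_cols} in {path.name}")
    t = _as_seconds(df[d["time"]].to_numpy(dtype=float), d["time_unit"])
    _check_monotone(t)
    fz = df[present].to_numpy(dtype=float).sum(axis=1)
    return RawForceRecord(t=t, fz=fz, fs=_infer_fs(t))


def write_fp_csv(rec: RawForceRecord, path, dialect: Mapping | None = None) -> None:
    d = {**DEFAULT_FP_DIALECT, **(dialect or {})}
    force_cols = d["force"]
    if isinstance(force_cols, str):
        force_cols = (force_cols,)
    df = pd.DataFrame({d["time"]: rec.t, force_cols[0]: rec.fz})
    df.to_csv(path, sep=d["delimiter"], index=False)


# ---------------------------------------------------------------------------
# Calibration


def estimate_gyro_bias(static: RawImuRecord, duration: float = 60.0) -> np.ndarray:
    """Per-axis gyroscope bias from a static trial: the mean over ``duration`` s."""
    if static.duration < duration - 1e-9:
        raise DataError(
            f"static record covers {static.duration:.1f}s < requested {duration}s"
        )
    sel = static.t <= static.t[0] + duration
    win = static.gyro[sel]
    if np.any(np.std(win, axis=0) >= 5.0):
        raise QualityError("gyroscope std >= 5 deg/s: device not stationary")
    return win.mean(axis=0)


def calibrate_accelerometer(axis_trials: Sequence[RawImuRecord]) -> CalibrationSet:
    """Offset + per-axis scale from three gravity-aligned static acquisitions.

    Trial ``k`` must have accelerometer axis ``k`` aligned with gravity
    (reading ≈ ±g) and the other two axes reading ≈ 0.  The off-axis means
    give the offsets; each aligned reading, offset-corrected, gives the scale
    mapping it onto g.  Corrected output is ``(raw − offset) · scale``.
    """
    if len(axis_trials) != 3:
        raise CalibrationError("exactly three single-axis trials are required")
    means = np.array([tr.acc.mean(axis=0) for tr in axis_trials])  # (trial, axis)
    for k in range(3):
        if abs(means[k, k]) < 0.5 * G:
            raise CalibrationError(
                f"trial {k}: aligned-axis mean {means[k, k]:.2f} m/s² is below 0.5 g; "
                "wrong orientation?"
            )
    offset = np.empty(3)
    for j in range(3):
        off_trials = [k for k in range(3) if k != j]
        offset[j] = means[off_trials, j].mean()
    scale = np.array([G / abs(means[k, k] - offset[k]) for k in range(3)])
    return CalibrationSet(accel_offset=offset, accel_scale=scale)


def apply_calibration(rec: RawImuRecord, cal: CalibrationSet) -> RawImuRecord:
    """Return a copy with calibrated accelerometer and bias-free gyroscope."""
    acc = (rec.acc - cal.accel_offset) * cal.accel_scale
    gyro = rec.gyro - cal.gyro_bias
    return replace(rec, acc=acc, gyro=gyro)


# ---------------------------------------------------------------------------
# Conversion to vertical acceleration traces


def _rotation_onto_z(v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit(v) onto +z (Rodrigues formula)."""
    u = v / np.linalg.norm(v)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(u, z))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        # antiparallel: rotate pi about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    kmat = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + s * kmat + (1 - c) * (kmat @ kmat)


def _resample_uniform(t: np.ndarray, x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Linear resampling onto a uniform grid at ``fs``; aborts on gaps > 3/fs."""
    dt = np.diff(t)
    if np.any(dt > 3.0 / fs):
        raise DataError(f"gap of {dt.max():.4f}s exceeds 3/fs; recording unusable")
    tu = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs)) + 1) / fs
    if x.ndim == 1:
        return tu, np.interp(tu, t, x)
    cols = [np.interp(tu, t, x[:, j]) for j in range(x.shape[1])]
    return tu, np.stack(cols, axis=1)


def to_vertical_accel(
    rec: RawImuRecord,
    cal: CalibrationSet | None = None,
    static_window: tuple[float, float] = (0.0, 1.0),
) -> AccelTrace:
    """World-vertical, gravity-free acceleration from a calibrated IMU record.

    The mean acceleration over ``static_window`` is taken as the gravity
    direction; the whole record is rotated so it maps onto +z (static tilt
    correction), g is subtracted from the vertical component, and the result
    is linearly resampled onto the nominal uniform grid.
    """
    if cal is not None:
        rec = apply_calibration(rec, cal)
    t0, t1 = static_window
    if t0 < rec.t[0] - 1e-9 or t1 > rec.t[-1] + 1e-9:
        raise DataError("static window lies outside the record")
    sel = (rec.t >= t0) & (rec.t <= t1)
    g_vec = rec.acc[sel].mean(axis=0)
    norm = float(np.linalg.norm(g_vec))
    if abs(norm - G) > 0.10 * G:
        raise CalibrationError(
            f"static acceleration norm {norm:.2f} m/s² differs from g by more "
            "than 10%: bad calibration or the device moved"
        )
    rot = _rotation_onto_z(g_vec)
    a_vert = (rec.acc @ rot.T)[:, 2] - G
    tu, au = _resample_uniform(rec.t, a_vert, rec.fs)
    return AccelTrace(t=tu, a=au, fs=rec.fs, source="SP")


def mass_from_fp(rec: RawForceRecord, static_window: tuple[float, float] = (0.0, 1.0)) -> float:
    """Body mass in kg: mean static vertical force divided by g."""
    t0, t1 = static_window
    if t0 < rec.t[0] - 1e-9 or t1 > rec.t[-1] + 1e-9:
        raise DataError("static window lies outside the record")
    win = rec.fz[(rec.t >= t0) & (rec.t <= t1)]
    if float(np.std(win)) >= 50.0:
        raise QualityError(f"static force std {np.std(win):.1f} N >= 50 N: unstable window")
    m = float(np.mean(win)) / G
    if m <= 0:
        raise QualityError("non-positive mass from static window")
    return m


def fp_to_accel(rec: RawForceRecord, m: float) -> AccelTrace:
    """Center-of-mass vertical acceleration from force: a = Fz/m − g."""
    if m <= 0:
        raise ValueError(f"mass must be positive, got {m}")
    tu, fzu = _resample_uniform(rec.t, rec.fz, rec.fs)
    return AccelTrace(t=tu, a=fzu / m - G, fs=rec.fs, source="FP")
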