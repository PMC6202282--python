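"""Loading and regularization of tracked positions and raw photometry.

Trajectory files are delimited text (comma or tab, auto-detected) with a
header row containing at least ``time``, ``x`` and ``y`` columns — the shape
of an Ethovision-style export.  Positions are arena-frame centimeters with
the origin at the arena center and y increasing upward.  Loading resamples
onto a uniform grid by linear interpolation; brief tracking losses (blank
coordinates or missing rows) up to 1 s are interpolated, longer gaps raise
:class:`~openarms.errors.DataQualityError`.

Photometry files come in two flavors: a two-column ``time,voltage`` table,
or a compact two-line header (``sample_rate=...`` and ``carrier_freq=...``)
followed by one voltage per line.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataQualityError, ParseError, ValidationError

MAX_GAP_S = 1.0


@dataclass
class Trajectory:
    """Uniformly sampled (time, x, y) path of one session.

    times are seconds from session start, strictly increasing and uniformly
    spaced at 1/sample_rate; x/y are finite arena-frame centimeters.
    """

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sample_rate: float
    arena: object = None  # ArenaSpec, kept untyped to avoid a cycle

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValidationError("times/x/y must have equal length")
        if len(self.times) < 2:
            raise ValidationError("a trajectory needs at least 2 samples")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("trajectory contains non-finite coordinates")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.max(np.abs(dt - 1.0 / self.sample_rate)) > 1e-6:
            raise ValidationError("times are not uniform at 1/sample_rate")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def session_length(self) -> float:
        """Session duration in seconds (each sample covers one frame)."""
        return self.n_samples * self.dt

    def path_length(self) -> float:
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())


@dataclass
class SpeedSeries:
    """Instantaneous speed (cm/s) aligned to a trajectory."""

    times: np.ndarray
    speed: np.ndarray
    smoothing_window: float
    sample_rate: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.times.shape != self.speed.shape:
            raise ValidationError("times and speed must have equal length")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class RawPhotometry:
    """Raw modulated photodetector voltage trace."""

    times: np.ndarray
    voltage: np.ndarray
    sample_rate: float
    carrier_freq: float = 80.0
    mean_power_note: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.times.shape != self.voltage.shape:
            raise ValidationError("times and voltage must have equal length")
        if self.sample_rate <= 2.0 * self.carrier_freq:
            raise ValidationError(
                f"sample_rate {self.sample_rate} Hz violates Nyquist for "
                f"carrier {self.carrier_freq} Hz"
            )


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=None, engine="python", skip_blank_lines=False)
    except Exception as exc:  # pandas raises many flavors; unify
        raise ParseError(f"{path}: could not parse delimited text ({exc})") from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def load_trajectory(path, arena=None, target_rate: float = 25.0) -> Trajectory:
    """Load a tracked-position file and resample to ``target_rate``.

    Gaps (blank coordinates or missing rows) of at most 1 s are linearly
    interpolated; longer gaps raise ``DataQualityError``.  Leading/trailing
    untracked rows are trimmed (there is nothing to interpolate from).
    """
    df = _read_table(path)
    for col in ("time", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if len(df) < 2:
        raise ParseError(f"{path}: need at least 2 rows")

    t = pd.to_numeric(df["time"], errors="coerce").to_numpy(dtype=float)
    x = pd.to_numeric(df["x"], errors="coerce").to_numpy(dtype=float)
    y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
    if np.any(~np.isfinite(t)):
        bad = int(np.flatnonzero(~np.isfinite(t))[0]) + 2  # 1-based + header
        raise ParseError(f"{path}: unparseable time value at line {bad}")
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 2
        raise ValidationError(f"{path}: non-monotone time at line {bad}")

    valid = np.isfinite(x) & np.isfinite(y)
    if valid.sum() < 2:
        raise DataQualityError(f"{path}: fewer than 2 tracked samples")
    tv, xv, yv = t[valid], x[valid], y[valid]
    gaps = np.diff(tv)
    if np.any(gaps > MAX_GAP_S + 1e-9):
        i = int(np.argmax(gaps))
        raise DataQualityError(
            f"{path}: tracking gap of {gaps[i]:.3f} s at t={tv[i]:.3f} s "
            f"exceeds the {MAX_GAP_S} s interpolation limit"
        )

    dt = 1.0 / target_rate
    n = int(np.floor((tv[-1] - tv[0]) / dt + 1e-9)) + 1
    new_t = tv[0] + np.arange(n) * dt
    new_x = np.interp(new_t, tv, xv)
    new_y = np.interp(new_t, tv, yv)
    return Trajectory(times=new_t, x=new_x, y=new_y, sample_rate=target_rate,
                      arena=arena)


def compute_speed(traj: Trajectory, smoothing_window: float = 0.2) -> SpeedSeries:
    """Instantaneous speed: frame-to-frame displacement * sample_rate, then
    a centered moving average over ``smoothing_window`` seconds (shrunken
    windows at the edges).  The result is rotation/translation invariant.
    """
    if smoothing_window < 0:
        raise ValidationError("smoothing_window must be >= 0")
    step = np.hypot(np.diff(traj.x), np.diff(traj.y)) * traj.sample_rate
    inst = np.concatenate((step, step[-1:])) if len(step) else np.zeros(1)
    w = max(1, int(round(smoothing_window * traj.sample_rate)))
    if w % 2 == 0:
        w += 1
    if w > 1:
        smoothed = (
            pd.Series(inst).rolling(w, center=True, min_periods=1).mean().to_numpy()
        )
    else:
        smoothed = inst
    return SpeedSeries(times=traj.times, speed=smoothed,
                       smoothing_window=smoothing_window,
                       sample_rate=traj.sample_rate)


def load_photometry(path, carrier_freq: float = 80.0) -> RawPhotometry:
    """Load a raw photometry voltage trace (either supported text format)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "=" in first and "," not in first.split("=")[0]:
        # two-line header: sample_rate=..., carrier_freq=..., then voltages
        with open(path) as fh:
            l1 = fh.readline().strip()
            l2 = fh.readline().strip()
            try:
                meta = dict(kv.split("=") for kv in (l1, l2))
                fs = float(meta["sample_rate"])
                fc = float(meta["carrier_freq"])
            except Exception as exc:
                raise ParseError(f"{path}: malformed photometry header") from exc
            try:
                v = np.loadtxt(fh, dtype=float, ndmin=1)
            except Exception as exc:
                raise ParseError(f"{path}: malformed voltage value ({exc})") from exc
        times = np.arange(len(v)) / fs
        return RawPhotometry(times=times, voltage=v, sample_rate=fs,
                             carrier_freq=fc)
    df = _read_table(path)
    for col in ("time", "voltage"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    t = df["time"].to_numpy(dtype=float)
    v = df["voltage"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return RawPhotometry(times=t, voltage=v, sample_rate=fs,
                         carrier_freq=carrier_freq)


def save_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"time": traj.times, "x": traj.x, "y": traj.y}).to_csv(
        path, index=False, float_format="%.6f"
    )


def save_photometry(raw: RawPhotometry, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"sample_rate={raw.sample_rate:g}\n")
        fh.write(f"carrier_freq={raw.carrier_freq:g}\n")
        np.savetxt(fh, raw.voltage, fmt="%.6f")
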