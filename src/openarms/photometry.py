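"""Lock-in style demodulation, df/f normalization, and peri-event analysis.

The excitation LED is modulated with an 80 Hz sinusoid, so the calcium-
dependent fluorescence rides on an 80 Hz carrier in the photodetector
voltage.  Demodulation recovers the slow envelope as short-time spectral
power integrated over a narrow band around the carrier (default 79-81 Hz).
The demodulated trace is normalized to df/f with a centered 1-minute
rolling average f around each point: dff = (f_n - f) / f.  Peri-event
matrices align df/f to behavioral events on a common grid (-20..+10 s at
10 Hz by default), and period means summarize three windows per event:
baseline [-15, -10] s, pre-movement [-8, -3] s, and movement
[peak, peak + 1] s (anchored at the movement's speed peak by default, or at
the zone entry itself with ``anchor='entry'``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .errors import ConfigError, DegenerateDataError, EmptyResultError, ValidationError
from .tracking import RawPhotometry

log = logging.getLogger(__name__)

DEFAULT_BAND = (79.0, 81.0)
DEFAULT_WINDOW = 0.5       # s, spectrogram frame length
DEFAULT_STEP = 0.25        # s, 50% overlap
DEFAULT_ROLLING = 60.0     # s, df/f rolling-average window
DEFAULT_PERI_WINDOW = (-20.0, 10.0)
DEFAULT_GRID_RATE = 10.0   # Hz
PERIODS = {"baseline": (-15.0, -10.0), "pre_movement": (-8.0, -3.0)}
MOVEMENT_PERIOD_LENGTH = 1.0  # s, beginning at the movement peak


@dataclass
class DemodSeries:
    """Demodulated band power at the carrier, at spectrogram frame centers."""

    times: np.ndarray
    power: np.ndarray
    band: tuple[float, float]
    window_length: float
    step: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.times.shape != self.power.shape:
            raise ValidationError("times and power must have equal length")


@dataclass
class DfFSeries:
    """Normalized fluorescence: dff[n] = (f_n - fbar_n) / fbar_n."""

    times: np.ndarray
    dff: np.ndarray
    rolling_window: float


@dataclass
class Event:
    """A behavioral alignment event (zone entry or movement onset)."""

    time: float
    kind: str = "movement_onset"
    peak_time: Optional[float] = None  # absolute time of the movement's speed peak


@dataclass
class PeriEventMatrix:
    """Events x time grid of df/f around each event."""

    offsets: np.ndarray            # seconds relative to event
    data: np.ndarray               # shape (n_events, len(offsets))
    events: list                   # retained Event objects, row-aligned
    n_dropped: int = 0

    @property
    def n_events(self) -> int:
        return self.data.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.data.mean(axis=0)


def _stft(raw: RawPhotometry, window_length: float, step: float):
    nperseg = int(round(window_length * raw.sample_rate))
    nstep = int(round(step * raw.sample_rate))
    if not 0 < nstep <= nperseg:
        raise ConfigError("step must satisfy 0 < step <= window_length")
    freqs, t, sxx = _signal.spectrogram(
        raw.voltage, fs=raw.sample_rate, window="hann", nperseg=nperseg,
        noverlap=nperseg - nstep, detrend="constant", scaling="density",
        mode="psd",
    )
    return freqs, raw.times[0] + t, sxx


def mean_spectrum(raw: RawPhotometry, window_length: float = DEFAULT_WINDOW,
                  step: float = DEFAULT_STEP):
    """Time-averaged short-time power spectrum (freqs, mean PSD)."""
    freqs, _, sxx = _stft(raw, window_length, step)
    return freqs, sxx.mean(axis=1)


def demodulate(raw: RawPhotometry, band: tuple[float, float] = DEFAULT_BAND,
               window_length: float = DEFAULT_WINDOW,
               step: float = DEFAULT_STEP) -> DemodSeries:
    """Short-time spectral power integrated over ``band``, per frame.

    The returned power is proportional to the squared carrier amplitude
    (so its square root tracks the fluorescence envelope linearly).
    """
    lo, hi = band
    nyq = raw.sample_rate / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ConfigError(f"band {band} must lie within (0, {nyq}) Hz")
    if window_length < 1.0 / (hi - lo):
        raise ConfigError(
            f"window_length {window_length} s cannot resolve a {hi - lo} Hz band"
        )
    freqs, t, sxx = _stft(raw, window_length, step)
    df = freqs[1] - freqs[0]
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():  # band narrower than one bin: take the nearest bin
        mask = np.zeros_like(freqs, dtype=bool)
        mask[int(np.argmin(np.abs(freqs - 0.5 * (lo + hi))))] = True
    power = sxx[mask].sum(axis=0) * df
    return DemodSeries(times=t, power=power, band=(lo, hi),
                       window_length=window_length, step=step)


def dff(demod: DemodSeries, rolling_window: float = DEFAULT_ROLLING) -> DfFSeries:
    """Normalize demodulated power to df/f with a centered rolling mean.

    The rolling mean is computed "around each data point" with shrunken
    windows at the edges.  df/f is invariant to any global gain k > 0.
    """
    p = demod.power
    if np.all(p <= 0):
        raise DegenerateDataError("demodulated power is identically zero")
    floor = 1e-12 * float(np.max(p))
    p = np.maximum(p, floor)
    w = max(1, int(round(rolling_window / demod.step)))
    if w % 2 == 0:
        w += 1
    fbar = pd.Series(p).rolling(w, center=True, min_periods=1).mean().to_numpy()
    return DfFSeries(times=demod.times, dff=(p - fbar) / fbar,
                     rolling_window=rolling_window)


def events_from_bouts(bouts) -> list[Event]:
    """Alignment events at movement-bout onsets (carrying the speed peak)."""
    return [Event(time=b.start, kind="movement_onset", peak_time=b.peak_time)
            for b in bouts]


def events_from_entries(entries, zone: str, bouts=None) -> list[Event]:
    """Alignment events at accepted entries into ``zone``.

    If ``bouts`` are given, each entry is annotated with the speed peak of
    the movement bout containing the entry (needed for the peak-anchored
    movement period); entries outside any bout keep ``peak_time=None``.
    """
    events = []
    for e in entries:
        if e.zone != zone:
            continue
        peak = None
        if bouts is not None:
            for b in bouts:
                if b.start - 1e-9 <= e.time <= b.end + 1e-9:
                    peak = b.peak_time
                    break
        events.append(Event(time=e.time, kind=f"{zone}_entry", peak_time=peak))
    return events


def peri_event(series: DfFSeries, events: Sequence[Event],
               window: tuple[float, float] = DEFAULT_PERI_WINDOW,
               grid_rate: float = DEFAULT_GRID_RATE) -> PeriEventMatrix:
    """Resample df/f around each event onto a common offset grid.

    Events whose window would extend past the recording are dropped (with a
    logged count).  Raises ``EmptyResultError`` if no event is usable.
    """
    lo, hi = window
    if not lo < hi:
        raise ConfigError("window must satisfy lo < hi")
    offsets = np.arange(0, round((hi - lo) * grid_rate) + 1) / grid_rate + lo
    t0, t1 = series.times[0], series.times[-1]
    rows, kept = [], []
    for ev in events:
        if ev.time + lo < t0 - 1e-9 or ev.time + hi > t1 + 1e-9:
            continue
        rows.append(np.interp(ev.time + offsets, series.times, series.dff))
        kept.append(ev)
    n_dropped = len(events) - len(kept)
    if n_dropped:
        log.info("peri_event: dropped %d/%d events outside recording margins",
                 n_dropped, len(events))
    if not rows:
        raise EmptyResultError("no events within the recording margins")
    return PeriEventMatrix(offsets=offsets, data=np.vstack(rows),
                           events=kept, n_dropped=n_dropped)


def _window_mean(row: np.ndarray, offsets: np.ndarray, lo: float, hi: float) -> float:
    m = (offsets >= lo - 1e-9) & (offsets < hi - 1e-9)
    if not m.any():
        raise ConfigError(f"period [{lo}, {hi}) s lies outside the peri-event grid")
    return float(row[m].mean())


def period_means(mat: PeriEventMatrix, periods: dict = None,
                 movement_length: float = MOVEMENT_PERIOD_LENGTH,
                 anchor: str = "peak") -> pd.Series:
    """Event-averaged mean df/f in the baseline / pre-movement / movement
    periods for one subject.

    The movement period begins at the movement's speed peak (``anchor=
    'peak'``) or at the event itself (``anchor='entry'``); events without a
    recorded peak fall back to the entry anchor.
    """
    if anchor not in ("peak", "entry"):
        raise ConfigError("anchor must be 'peak' or 'entry'")
    periods = dict(PERIODS if periods is None else periods)
    out = {name: float(np.mean([_window_mean(row, mat.offsets, lo, hi)
                                for row in mat.data]))
           for name, (lo, hi) in periods.items()}
    mv, skipped = [], 0
    grid_hi = mat.offsets[-1] + (mat.offsets[1] - mat.offsets[0])
    for row, ev in zip(mat.data, mat.events):
        if anchor == "peak" and ev.peak_time is not None:
            start = ev.peak_time - ev.time
        else:
            start = 0.0
        if start + movement_length > grid_hi + 1e-9:
            skipped += 1  # movement peak beyond the peri-event grid
            continue
        mv.append(_window_mean(row, mat.offsets, start, start + movement_length))
    if not mv:
        raise ConfigError("no event's movement period fits the peri-event grid")
    if skipped:
        log.info("period_means: movement window off-grid for %d/%d events",
                 skipped, mat.n_events)
    out["movement"] = float(np.mean(mv))
    s = pd.Series(out)
    s.attrs["n_events"] = mat.n_events
    return s


def transient_amplitude(mat: PeriEventMatrix,
                        search_window: tuple[float, float] = (-1.0, 4.0),
                        pre_window: tuple[float, float] = (-3.0, -1.0)) -> float:
    """Event-averaged transient amplitude in df/f units.

    Peak of the event-averaged trace near the event, referenced to the mean
    df/f just before onset.  The local reference matters because the 1-min
    rolling normalization folds the session-average transient mass into f,
    which offsets the whole trace downward; the level immediately pre-onset
    shares that offset, so the difference recovers the transient's
    fractional amplitude nearly unbiased.
    """
    tr = mat.mean_trace()
    sel = (mat.offsets >= search_window[0]) & (mat.offsets <= search_window[1])
    pre = (mat.offsets >= pre_window[0]) & (mat.offsets <= pre_window[1])
    if not (sel.any() and pre.any()):
        raise ConfigError("windows lie outside the peri-event grid")
    return float(tr[sel].max() - tr[pre].mean())


def period_table(per_subject: dict) -> pd.DataFrame:
    """Stack per-subject ``period_means`` Series into a subjects x periods
    DataFrame ready for the repeated-measures ANOVA."""
    return pd.DataFrame({k: v for k, v in per_subject.items()}).T[
        ["baseline", "pre_movement", "movement"]
    ]
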