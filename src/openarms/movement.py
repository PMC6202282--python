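"""Movement-bout segmentation, sub-region attribution, and session features.

A movement bout is a maximal run of samples at or above a speed threshold
(default 2 cm/s, inclusive) lasting at least a minimum duration (default
500 ms).  A run of n samples at rate fs counts as n/fs seconds (each sample
covers one frame interval), so at 25 Hz the 500 ms rule is 13 frames.

A bout is attributed to an arena sub-region if it either spends at least
500 ms in that region during the bout, or lies entirely within it; a bout
crossing regions can therefore be attributed to more than one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np

from .arena import ZoneSeries, _runs
from .errors import ValidationError
from .tracking import SpeedSeries, Trajectory, compute_speed

SPEED_THRESHOLD = 2.0   # cm/s, inclusive
MIN_BOUT_DURATION = 0.5  # s
MIN_ZONE_TIME = 0.5      # s, for sub-region attribution

_EPS = 1e-9


@dataclass
class MovementBout:
    """One supra-threshold locomotion episode."""

    start: float
    end: float
    duration: float
    distance: float
    mean_speed: float
    peak_speed: float
    peak_time: float
    i0: int                      # first sample index (inclusive)
    i1: int                      # last sample index (inclusive)
    zones_attributed: frozenset = field(default_factory=frozenset)


@dataclass
class BehavioralFeatures:
    """Per-session behavioral feature set for the avoidance regression."""

    speed_while_moving: float
    mean_bout_duration: float
    n_movements: int
    total_distance: float
    n_movements_into_open: int
    time_in_open_pct: float
    zone_movement_counts: dict
    zone_times: dict
    n_double_attributed: int  # bouts attributed to both open and closed classes

    def to_dict(self) -> dict:
        d = {
            "speed_while_moving": self.speed_while_moving,
            "mean_bout_duration": self.mean_bout_duration,
            "n_movements": self.n_movements,
            "total_distance": self.total_distance,
            "n_movements_into_open": self.n_movements_into_open,
            "time_in_open_pct": self.time_in_open_pct,
            "zone_movement_counts": dict(self.zone_movement_counts),
            "zone_times": dict(self.zone_times),
            "n_double_attributed": self.n_double_attributed,
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def detect_bouts(speed: SpeedSeries, threshold: float = SPEED_THRESHOLD,
                 min_duration: float = MIN_BOUT_DURATION,
                 gap_tolerance: float = 0.0) -> list[MovementBout]:
    """Segment movement bouts from a speed series.

    ``threshold`` is compared inclusively ("2 cm/s or faster").  With the
    default ``gap_tolerance`` of 0 a single sub-threshold frame splits a
    bout; a positive tolerance merges supra-threshold runs separated by
    sub-threshold gaps of at most that many seconds.
    """
    if threshold <= 0:
        raise ValidationError("threshold must be > 0")
    dt = speed.dt
    mask = speed.speed >= threshold
    runs = [(s, e) for s, e, lab in _runs(mask) if lab]
    if gap_tolerance > 0 and runs:
        merged = [list(runs[0])]
        for s, e in runs[1:]:
            if (s - merged[-1][1]) * dt <= gap_tolerance + _EPS:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        runs = [tuple(r) for r in merged]
    bouts = []
    for s, e in runs:
        dur = (e - s) * dt
        if dur + _EPS < min_duration:
            continue
        seg = speed.speed[s:e]
        dist = float(seg.sum()) * dt
        ipk = int(np.argmax(seg))  # earliest sample on ties
        bouts.append(MovementBout(
            start=float(speed.times[s]),
            end=float(speed.times[e - 1]) + dt,
            duration=dur,
            distance=dist,
            mean_speed=dist / dur,
            peak_speed=float(seg[ipk]),
            peak_time=float(speed.times[s + ipk]),
            i0=s,
            i1=e - 1,
        ))
    return bouts


def _zone_occupancy(labels: np.ndarray, dt: float) -> dict:
    vals, counts = np.unique(labels, return_counts=True)
    return {str(v): float(c) * dt for v, c in zip(vals, counts)}


def attribute_bouts(bouts: list[MovementBout], zones: ZoneSeries,
                    min_zone_time: float = MIN_ZONE_TIME) -> list[MovementBout]:
    """Fill ``zones_attributed`` for each bout.

    A zone is attributed iff the bout spends >= ``min_zone_time`` in it, or
    the bout lies entirely within it.  Returns the same list, mutated.
    """
    dt = zones.dt
    for b in bouts:
        occ = _zone_occupancy(zones.zone[b.i0:b.i1 + 1], dt)
        attributed = {z for z, t in occ.items() if t + _EPS >= min_zone_time}
        if len(occ) == 1:
            attributed.update(occ)
        b.zones_attributed = frozenset(attributed)
    return bouts


def extract_features(traj: Trajectory, zones: ZoneSeries,
                     bouts: list[MovementBout],
                     speed: SpeedSeries | None = None,
                     open_labels=None) -> BehavioralFeatures:
    """Compute the five regression features (plus per-zone breakdowns).

    ``speed_while_moving`` is the distance-weighted mean speed over bout
    samples; ``total_distance`` is the whole-session path length;
    ``time_in_open_pct`` counts samples labeled with ``open_labels``
    (defaults to the arena's open/center class).
    """
    if speed is None:
        speed = compute_speed(traj)
    if open_labels is None:
        open_labels = zones.arena.open_labels if zones.arena is not None else ("open",)
    open_labels = tuple(open_labels)

    dt = traj.dt
    bout_mask = np.zeros(traj.n_samples, dtype=bool)
    for b in bouts:
        bout_mask[b.i0:b.i1 + 1] = True
    v = speed.speed[bout_mask]
    swm = float((v * v).sum() / v.sum()) if v.sum() > 0 else 0.0

    counts: dict[str, int] = {}
    for b in bouts:
        for z in b.zones_attributed:
            counts[z] = counts.get(z, 0) + 1
    n_open = sum(1 for b in bouts
                 if any(z in b.zones_attributed for z in open_labels))
    closed_like = {"closed", "surround"}
    n_double = sum(
        1 for b in bouts
        if any(z in b.zones_attributed for z in open_labels)
        and any(z in b.zones_attributed for z in closed_like)
    )
    open_time = float(np.isin(zones.zone, list(open_labels)).sum()) * dt
    return BehavioralFeatures(
        speed_while_moving=swm,
        mean_bout_duration=float(np.mean([b.duration for b in bouts])) if bouts else 0.0,
        n_movements=len(bouts),
        total_distance=traj.path_length(),
        n_movements_into_open=n_open,
        time_in_open_pct=100.0 * open_time / traj.session_length,
        zone_movement_counts=counts,
        zone_times=_zone_occupancy(zones.zone, dt),
        n_double_attributed=n_double,
    )
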