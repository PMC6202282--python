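"""Arena geometry and per-sample zone classification.

Two arenas are supported:

* **Elevated zero maze** — an annular track (57 cm outer diameter, 7 cm
  wide) with two walled ("closed") arms and two open arms.  Zones are
  defined purely by angular position: a 30-degree arc centered on each of
  the four open/closed boundaries is a "transition" zone, which allocates
  120 degrees in total to each of the open, closed and transition classes.
* **Open field** — a square box whose concentric "center" region covers a
  configurable fraction (default 65%) of the arena *area*, i.e. a square of
  side ``side * sqrt(center_area_fraction)``.

Zone labels partition the arena exhaustively and exclusively, so the time
spent across zones always sums to the session length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigError, ValidationError

ZERO_MAZE = "zero_maze"
OPEN_FIELD = "open_field"

ZM_LABELS = ("open", "closed", "transition")
OF_LABELS = ("center", "surround")


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of one behavioral arena.

    Zero-maze fields: ``outer_diameter`` (cm), ``annulus_width`` (cm),
    ``closed_arm_centers`` (two opposed angles, degrees), ``transition_arc``
    (degrees, split symmetrically around each open/closed boundary) and
    ``transition_zones`` (when False the four transition arcs are split at
    their centers between the adjoining open and closed arms, 180 degrees
    each — the convention used when only open/closed occupancy is reported).

    Open-field fields: ``side`` (cm) and ``center_area_fraction``
    (fraction of arena *area* covered by the concentric center square).
    """

    kind: str
    outer_diameter: float = 57.0
    annulus_width: float = 7.0
    closed_arm_centers: tuple[float, float] = (90.0, 270.0)
    transition_arc: float = 30.0
    transition_zones: bool = True
    side: float = 40.0
    center_area_fraction: float = 0.65

    def __post_init__(self):
        if self.kind not in (ZERO_MAZE, OPEN_FIELD):
            raise ConfigError(f"unknown arena kind {self.kind!r}")
        if self.kind == ZERO_MAZE:
            a, b = self.closed_arm_centers
            if abs(((b - a) % 360.0) - 180.0) > 1e-9:
                raise ConfigError("closed arm centers must be opposed (180 deg apart)")
            if not 0.0 < self.transition_arc < 90.0:
                raise ConfigError("transition_arc must lie in (0, 90) degrees")
        else:
            if not 0.0 < self.center_area_fraction < 1.0:
                raise ConfigError("center_area_fraction must lie in (0, 1)")

    # --- derived geometry -------------------------------------------------
    @property
    def annulus_radius(self) -> float:
        """Radius of the annulus centerline (cm)."""
        return (self.outer_diameter - self.annulus_width) / 2.0

    @property
    def center_half_width(self) -> float:
        """Half side of the open-field center square (cm)."""
        return self.side * math.sqrt(self.center_area_fraction) / 2.0

    @property
    def labels(self) -> tuple[str, ...]:
        if self.kind == ZERO_MAZE:
            return ZM_LABELS if self.transition_zones else ("open", "closed")
        return OF_LABELS

    @property
    def open_labels(self) -> tuple[str, ...]:
        """Labels counted as the 'risky' open region of this arena."""
        return ("open",) if self.kind == ZERO_MAZE else ("center",)

    @classmethod
    def zero_maze(cls, **kw) -> "ArenaSpec":
        return cls(kind=ZERO_MAZE, **kw)

    @classmethod
    def open_field(cls, side: float = 40.0, **kw) -> "ArenaSpec":
        return cls(kind=OPEN_FIELD, side=side, **kw)

    def without_transitions(self) -> "ArenaSpec":
        return replace(self, transition_zones=False)


@dataclass
class ZoneSeries:
    """Per-sample categorical zone label aligned to a trajectory."""

    times: np.ndarray
    zone: np.ndarray  # array of str labels, same length as times
    arena: ArenaSpec

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.zone = np.asarray(self.zone)
        if self.times.shape != self.zone.shape:
            raise ValidationError("times and zone must have equal length")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 0.0

    def time_in(self, labels: Sequence[str]) -> float:
        """Total occupancy time (s) of the given labels (sample count * dt)."""
        return float(np.isin(self.zone, list(labels)).sum()) * self.dt


@dataclass
class ZoneEntry:
    """One accepted entry into a zone (after dwell debouncing)."""

    time: float
    zone: str
    from_zone: Optional[str]
    dwell: float


def _angles_deg(x, y) -> np.ndarray:
    return np.degrees(np.arctan2(y, x)) % 360.0


def _angular_distance(a, b) -> np.ndarray:
    d = np.abs(np.asarray(a) - b) % 360.0
    return np.minimum(d, 360.0 - d)


def classify_zero_maze(x, y, spec: ArenaSpec):
    """Classify point(s) on the zero maze by angular sector.

    Radial position is ignored: the maze is an annulus and zones are defined
    in degrees.  Returns a scalar label for scalar input, else an array.
    ``d`` below is the angular distance to the nearest closed-arm center;
    with a 30-degree transition arc, closed occupies d <= 30, open d >= 60,
    transition in between (120 degrees per class in total).
    """
    scalar = np.isscalar(x) and np.isscalar(y)
    ang = _angles_deg(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    d = np.minimum(
        _angular_distance(ang, spec.closed_arm_centers[0]),
        _angular_distance(ang, spec.closed_arm_centers[1]),
    )
    half = spec.transition_arc / 2.0
    if spec.transition_zones:
        out = np.where(d <= 45.0 - half, "closed",
                       np.where(d >= 45.0 + half, "open", "transition"))
    else:
        out = np.where(d <= 45.0, "closed", "open")
    return out.item() if scalar else out


def classify_open_field(x, y, spec: ArenaSpec):
    """Classify point(s) in the open field: center iff max(|x|,|y|) <= h."""
    scalar = np.isscalar(x) and np.isscalar(y)
    h = spec.center_half_width
    m = np.maximum(np.abs(np.asarray(x, dtype=float)), np.abs(np.asarray(y, dtype=float)))
    out = np.where(m <= h, "center", "surround")
    return out.item() if scalar else out


def classify(x, y, spec: ArenaSpec):
    if spec.kind == ZERO_MAZE:
        return classify_zero_maze(x, y, spec)
    return classify_open_field(x, y, spec)


def zone_series(traj, spec: ArenaSpec) -> ZoneSeries:
    """Per-sample zone classification of a trajectory."""
    labels = classify(traj.x, traj.y, spec)
    return ZoneSeries(times=traj.times, zone=np.asarray(labels), arena=spec)


def _runs(labels: np.ndarray):
    """Yield (start_index, end_index_exclusive, label) for maximal runs."""
    n = len(labels)
    if n == 0:
        return
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        yield int(s), int(e), labels[s]


def detect_entries(zones: ZoneSeries, min_dwell: float = 0.5) -> list[ZoneEntry]:
    """Detect zone entries as first samples of runs lasting >= ``min_dwell``.

    Runs shorter than ``min_dwell`` are merged into the surrounding
    occupancy (they neither register an entry nor end the previous one);
    consecutive accepted runs of the same label collapse into one entry.
    A run of n samples at rate fs counts as n/fs seconds.  The first
    accepted run is itself an entry with ``from_zone=None``.
    """
    if min_dwell < 0:
        raise ValidationError("min_dwell must be >= 0")
    dt = zones.dt
    accepted: list[tuple[int, str]] = []  # (start index, label)
    for s, e, lab in _runs(zones.zone):
        if (e - s) * dt + 1e-9 >= min_dwell:
            if accepted and accepted[-1][1] == lab:
                continue  # same zone continues across a short excursion
            accepted.append((s, lab))
    entries: list[ZoneEntry] = []
    t_end = zones.times[-1] + dt if len(zones.times) else 0.0
    for i, (s, lab) in enumerate(accepted):
        t0 = float(zones.times[s])
        t1 = float(zones.times[accepted[i + 1][0]]) if i + 1 < len(accepted) else t_end
        entries.append(ZoneEntry(
            time=t0,
            zone=str(lab),
            from_zone=str(accepted[i - 1][1]) if i > 0 else None,
            dwell=t1 - t0,
        ))
    return entries
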