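"""YAML pipeline configuration.

One flat file holds the arena geometry and the tunable analysis parameters
(movement thresholds, photometry windows, closed-loop protocol, synthesis
settings).  ``default_config()`` returns the full dictionary with defaults;
``load_config`` overlays a YAML file on top of it; ``arena_from_config``
builds the :class:`~openarms.arena.ArenaSpec`.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .arena import ArenaSpec
from .errors import ConfigError

DEFAULTS = {
    "arena": {
        "kind": "zero_maze",
        "outer_diameter": 57.0,
        "annulus_width": 7.0,
        "closed_arm_centers": [90.0, 270.0],
        "transition_arc": 30.0,
        "transition_zones": "on",   # "off" splits transition arcs open/closed
        "side": 40.0,
        "center_area_fraction": 0.65,
    },
    "tracking": {
        "target_rate": 25.0,        # Hz; tracking export rates vary
        "speed_smoothing_window": 0.2,  # s
    },
    "movement": {
        "speed_threshold": 2.0,     # cm/s, inclusive
        "min_bout_duration": 0.5,   # s
        "gap_tolerance": 0.0,       # s of sub-threshold gap merged into a bout
        "min_zone_time": 0.5,       # s for sub-region attribution
        "entry_min_dwell": 0.5,     # s debounce for zone entries
    },
    "photometry": {
        "band": [79.0, 81.0],       # Hz
        "window_length": 0.5,       # s spectrogram frame
        "step": 0.25,               # s frame step (50% overlap)
        "rolling_window": 60.0,     # s df/f rolling average
        "peri_window": [-20.0, 10.0],
        "grid_rate": 10.0,          # Hz peri-event grid
        "movement_anchor": "peak",  # or "entry"
    },
    "closed_loop": {
        "n_per_type": 10,
        "min_dwell": 0.5,
        "stim_duration": 2.0,
        "refractory": 2.0,
        "seed": 0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in (extra or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh)
    if user is not None and not isinstance(user, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    return _merge(DEFAULTS, user or {})


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def arena_from_config(cfg: dict) -> ArenaSpec:
    a = cfg["arena"]
    flag = str(a.get("transition_zones", "on")).lower()
    if flag not in ("on", "off", "true", "false"):
        raise ConfigError(f"transition_zones must be on/off, got {flag!r}")
    common = dict(
        transition_zones=flag in ("on", "true"),
        outer_diameter=float(a["outer_diameter"]),
        annulus_width=float(a["annulus_width"]),
        closed_arm_centers=tuple(float(v) for v in a["closed_arm_centers"]),
        transition_arc=float(a["transition_arc"]),
        side=float(a["side"]),
        center_area_fraction=float(a["center_area_fraction"]),
    )
    return ArenaSpec(kind=a["kind"], **common)
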