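"""Ground-truthed synthetic sessions: behavior and photometry.

The behavior model is semi-Markov: the animal alternates rest epochs
(position jitter far below the movement threshold) with movement bouts.
On the zero maze movement is angular along the annulus centerline: bouts
either wander within the core of the current arm or cross into the
adjacent arm, entering the open arms with probability ``p_enter_open``
(and returning to a closed arm with probability ``p_return_closed``).  In
the open field bouts are straight segments toward sampled destinations in
the center (probability ``p_enter_open``) or in the wall-hugging surround
frame, routed around the center square.

Kinematics are quantized so that every within-bout frame displacement is
exactly ``speed * dt`` (per-bout speeds are adjusted so each path is an
integer number of frames, and wander reflections happen on the step grid).
Every scripted bout therefore survives the 2 cm/s / 500 ms detection rule
intact, which is what makes exact bout-count recovery possible on
noiseless sessions.

Photometry emulates the modulated-excitation recording: a GCaMP6s-like
transient kernel (fast rise, 1-2 s decay) is triggered at movement onsets
(optionally jittered, emulating the disorganized KO-like phenotype), rides
on a slow exponential bleaching baseline, modulates an 80 Hz carrier, and
is corrupted by broadband noise.  Transient amplitudes are expressed as the
fractional change of the demodulated carrier-band power — the quantity that
df/f normalizes — so the generator's ground truth and the pipeline's df/f
share units (the emitted optical envelope is the square root of that power
envelope).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from . import movement as _movement
from .arena import ArenaSpec, ZoneSeries, classify, detect_entries, zone_series
from .errors import ConfigError, ValidationError
from .tracking import RawPhotometry, Trajectory, save_photometry, save_trajectory

_EPS = 1e-9


@dataclass
class BehaviorConfig:
    """Parameters of the semi-Markov rest/move behavior model."""

    arena: ArenaSpec
    session_length: float = 600.0       # s
    sample_rate: float = 25.0           # Hz
    bout_rate_per_min: float = 5.0      # movement bouts per minute
    rest_cv: float = 0.2                # lognormal cv of rest durations
    bout_duration_median: float = 1.6   # s, within-arm wander bouts
    bout_duration_sigma: float = 0.35   # lognormal sigma of wander durations
    speed_mean: float = 8.0             # cm/s while moving
    speed_sd: float = 1.5
    speed_min: float = 3.5
    speed_max: float = 12.0
    p_enter_open: float = 0.35          # P(cross into open/center at a bout)
    p_return_closed: float = 0.75       # P(return toward closed/surround)
    rest_noise_sd: float = 0.02         # cm, per-coordinate tracking jitter at rest
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_enter_open, self.p_return_closed):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.bout_duration_median <= 0 or self.speed_mean <= 0:
            raise ConfigError("distributions must be positive")
        if self.rest_mean < 1.0:
            raise ConfigError(
                f"bout_rate_per_min={self.bout_rate_per_min} leaves "
                f"{self.rest_mean:.2f} s mean rest; bouts would overlap")

    @property
    def mean_bout_duration(self) -> float:
        """Approximate expected bout duration (wander/crossing mix)."""
        wander = self.bout_duration_median * math.exp(self.bout_duration_sigma ** 2 / 2)
        if self.arena.kind == "zero_maze":
            crossing = (math.pi / 2) * self.arena.annulus_radius / self.speed_mean
        else:
            crossing = 0.6 * self.arena.side / self.speed_mean
        p_cross = 0.5 * (self.p_enter_open + self.p_return_closed)
        return (1 - p_cross) * wander + p_cross * crossing

    @property
    def rest_mean(self) -> float:
        return 60.0 / self.bout_rate_per_min - self.mean_bout_duration


@dataclass
class PhotometryConfig:
    """Parameters of the modulated-excitation photometry model."""

    carrier_freq: float = 80.0     # Hz
    sample_rate: float = 1000.0    # Hz
    amplitude: float = 0.06        # fractional demodulated-power transient
    amplitude_cv: float = 0.0      # per-transient lognormal cv
    rise_tau: float = 0.2          # s (GCaMP6s-like onset)
    decay_tau: float = 1.5         # s (GCaMP6s-like decay)
    jitter_sd: float = 0.0         # s; 0 = movement-locked, ~4 = disorganized
    bleach_tau: float = 1800.0     # s, slow exponential bleaching
    baseline: float = 1.0          # arbitrary power units
    noise_sd: float = 0.08         # additive voltage noise (a.u.)
    kernel_support: float = 8.0    # s, transient kernel truncation
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if not self.decay_tau > self.rise_tau > 0:
            raise ConfigError("need decay_tau > rise_tau > 0")
        if self.sample_rate <= 2.0 * self.carrier_freq:
            raise ConfigError(
                f"sample_rate {self.sample_rate} Hz violates Nyquist for "
                f"carrier {self.carrier_freq} Hz")


@dataclass
class GroundTruth:
    """Everything the generator knows about one session."""

    # behavior
    bout_windows: list = field(default_factory=list)    # (i0, i1) inclusive
    bout_start_times: list = field(default_factory=list)
    bout_end_times: list = field(default_factory=list)
    bout_zones: list = field(default_factory=list)      # attributed zone sets
    zone_labels: Optional[np.ndarray] = None            # latent per-sample labels
    entries: list = field(default_factory=list)
    n_movements: int = 0
    n_movements_into_open: int = 0
    time_in_open_pct: float = 0.0
    session_length: float = 0.0
    sample_rate: float = 0.0
    # photometry
    transient_onsets_nominal: list = field(default_factory=list)
    transient_onsets: list = field(default_factory=list)  # after jitter
    transient_amplitudes: list = field(default_factory=list)
    # phenotype parameters used
    behavior_config: Optional[BehaviorConfig] = None
    photometry_config: Optional[PhotometryConfig] = None


# ---------------------------------------------------------------------------
# kinematic building blocks (all produce exact v*dt frame displacements)
# ---------------------------------------------------------------------------

def _quantized_steps(distance: float, v: float, dt: float,
                     vmin: float, vmax: float) -> tuple[int, float]:
    """Frame count and adjusted speed so distance = n * v_adj * dt exactly."""
    n_min = max(1, int(math.ceil(distance / (vmax * dt) - _EPS)))
    n_max = max(n_min, int(math.floor(distance / (vmin * dt) + _EPS)))
    n = min(max(int(round(distance / (v * dt))), n_min), n_max)
    return n, distance / (n * dt)


def _wander_1d(u0: float, lo: float, hi: float, step: float, n: int) -> np.ndarray:
    """Reflected walk on the step grid inside [lo, hi]: consecutive samples
    always differ by exactly ``step`` (reflections land on grid points)."""
    lo_q = u0 - math.floor((u0 - lo) / step + _EPS) * step
    hi_q = u0 + math.floor((hi - u0) / step + _EPS) * step
    span = hi_q - lo_q
    if span < step:  # degenerate core; oscillate in place around u0
        k = np.arange(1, n + 1)
        return u0 + step * (k % 2)
    u = u0 + step * np.arange(1, n + 1)
    m = np.mod(u - lo_q, 2.0 * span)
    return lo_q + np.minimum(m, 2.0 * span - m)


def _segment_hits_square(p0: np.ndarray, p1: np.ndarray, half: float) -> bool:
    """True if the open segment p0->p1 intersects the square |x|,|y| <= half."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for i in range(2):
        if abs(d[i]) < 1e-12:
            if abs(p0[i]) > half:
                return False
            continue
        ta = (-half - p0[i]) / d[i]
        tb = (half - p0[i]) / d[i]
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return False
    return True


# ---------------------------------------------------------------------------
# trajectory generation
# ---------------------------------------------------------------------------

def _truth_from_path(x, y, bout_windows, cfg: BehaviorConfig) -> GroundTruth:
    spec = cfg.arena
    dt = 1.0 / cfg.sample_rate
    labels = np.asarray(classify(x, y, spec))
    times = np.arange(len(x)) * dt
    zones = ZoneSeries(times=times, zone=labels, arena=spec)
    open_labels = spec.open_labels
    bout_zone_sets = []
    n_open = 0
    for i0, i1 in bout_windows:
        occ = _movement._zone_occupancy(labels[i0:i1 + 1], dt)
        attributed = {z for z, t in occ.items()
                      if t + _EPS >= _movement.MIN_ZONE_TIME}
        if len(occ) == 1:
            attributed.update(occ)
        bout_zone_sets.append(frozenset(attributed))
        if any(z in attributed for z in open_labels):
            n_open += 1
    entries = detect_entries(zones, min_dwell=0.5)
    open_time = float(np.isin(labels, list(open_labels)).sum()) * dt
    return GroundTruth(
        bout_windows=list(bout_windows),
        bout_start_times=[times[i0] for i0, _ in bout_windows],
        bout_end_times=[times[i1] + dt for _, i1 in bout_windows],
        bout_zones=bout_zone_sets,
        zone_labels=labels,
        entries=entries,
        n_movements=len(bout_windows),
        n_movements_into_open=n_open,
        time_in_open_pct=100.0 * open_time / (len(x) * dt),
        session_length=len(x) * dt,
        sample_rate=cfg.sample_rate,
        behavior_config=cfg,
    )


def _gen_zero_maze(cfg: BehaviorConfig, rng) -> tuple[np.ndarray, list]:
    spec = cfg.arena
    r = spec.annulus_radius
    dt = 1.0 / cfg.sample_rate
    n_total = int(round(cfg.session_length * cfg.sample_rate))
    core_half = 45.0 - spec.transition_arc / 2.0 - 5.0  # stay 5 deg off transition
    closed = list(spec.closed_arm_centers)
    opens = [(c + 90.0) % 360.0 for c in closed]

    sigma = math.sqrt(math.log(1.0 + cfg.rest_cv ** 2))
    mu = math.log(cfg.rest_mean) - sigma ** 2 / 2.0

    theta_parts: list[np.ndarray] = []
    bouts: list[tuple[int, int]] = []
    pos = 0
    theta = closed[0]
    arm_center, arm_is_closed = closed[0], True

    def emit_rest(duration):
        nonlocal pos
        n = max(1, int(round(duration * cfg.sample_rate)))
        theta_parts.append(np.full(n, theta))
        pos += n

    emit_rest(float(rng.lognormal(mu, sigma)))
    while pos < n_total:
        # re-anchor the angle branch near the current arm center (positions
        # are mod 360; this only keeps the 1-D walk coordinates contiguous)
        theta = arm_center + ((theta - arm_center + 180.0) % 360.0 - 180.0)
        v = float(np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd),
                          cfg.speed_min, cfg.speed_max))
        cross = rng.random() < (cfg.p_enter_open if arm_is_closed
                                else cfg.p_return_closed)
        start = pos
        if cross:
            direction = 1 if rng.random() < 0.5 else -1
            target_center = (arm_center + direction * 90.0) % 360.0
            target = target_center + float(rng.uniform(-8.0, 8.0))
            delta = (target - theta + 180.0) % 360.0 - 180.0
            arc = abs(math.radians(delta)) * r
            n, v_adj = _quantized_steps(arc, v, dt, cfg.speed_min, cfg.speed_max)
            step_deg = math.degrees(v_adj * dt / r)
            seg = theta + math.copysign(1.0, delta) * step_deg * np.arange(1, n + 1)
            theta = float(seg[-1])
            arm_center, arm_is_closed = target_center, not arm_is_closed
        else:
            dur = float(rng.lognormal(math.log(cfg.bout_duration_median),
                                      cfg.bout_duration_sigma))
            n = max(int(round(dur * cfg.sample_rate)),
                    int(math.ceil(0.7 * cfg.sample_rate)))
            step_deg = math.degrees(v * dt / r)
            lo, hi = arm_center - core_half, arm_center + core_half
            seg = _wander_1d(theta, lo, hi, step_deg, n)
            theta = float(seg[-1])
        if start + len(seg) > n_total - 2:
            break  # drop an incomplete trailing bout; pad with rest below
        theta_parts.append(seg)
        pos += len(seg)
        bouts.append((start, pos - 1))
        emit_rest(float(rng.lognormal(mu, sigma)))

    theta_all = np.concatenate(theta_parts)[:n_total]
    if len(theta_all) < n_total:
        theta_all = np.concatenate(
            [theta_all, np.full(n_total - len(theta_all), theta_all[-1])])
    rad = np.radians(theta_all)
    return np.column_stack([r * np.cos(rad), r * np.sin(rad)]), bouts


def _frame_side(q: np.ndarray) -> int:
    """Side of the surround frame a point sits on: 0=x+, 1=y+, 2=x-, 3=y-."""
    if abs(q[0]) >= abs(q[1]):
        return 0 if q[0] > 0 else 2
    return 1 if q[1] > 0 else 3


def _ring_waypoints(p: np.ndarray, dest: np.ndarray, corner: float) -> list:
    """Corner waypoints routing a surround-to-surround move around the
    center square.  Corner k sits between frame sides k and k+1 (mod 4);
    every leg of the returned route shares a frame side with both of its
    endpoints, so its dominant coordinate never drops below the band and
    the route cannot intersect the center.
    """
    corners = [np.array([corner, corner]), np.array([-corner, corner]),
               np.array([-corner, -corner]), np.array([corner, -corner])]
    a, b = _frame_side(p), _frame_side(dest)
    if a == b:
        return []
    n_ccw = (b - a) % 4
    n_cw = (a - b) % 4
    if n_ccw <= n_cw:
        ks = [(a + i) % 4 for i in range(n_ccw)]
    else:
        ks = [(a - 1 - i) % 4 for i in range(n_cw)]
    return [corners[k] for k in ks]


def _gen_open_field(cfg: BehaviorConfig, rng) -> tuple[np.ndarray, list]:
    spec = cfg.arena
    dt = 1.0 / cfg.sample_rate
    n_total = int(round(cfg.session_length * cfg.sample_rate))
    h = spec.center_half_width
    s2 = spec.side / 2.0
    wall_margin = min(1.0, (s2 - h) / 4.0)
    band_lo, band_hi = h + wall_margin, s2 - wall_margin
    corner = (h + s2) / 2.0

    sigma = math.sqrt(math.log(1.0 + cfg.rest_cv ** 2))
    mu = math.log(cfg.rest_mean) - sigma ** 2 / 2.0

    def sample_surround():
        for _ in range(200):
            q = rng.uniform(-band_hi, band_hi, size=2)
            if np.max(np.abs(q)) >= band_lo:
                return q
        return np.array([band_hi, band_hi])

    # center destinations deep enough that the in-center leg of an entering
    # bout lasts >= 0.5 s at any permitted speed
    center_r = 0.5 * h
    v_center_max = min(cfg.speed_max, max(cfg.speed_min + 0.5,
                                          (h - center_r) / 0.55))

    parts: list[np.ndarray] = []
    bouts: list[tuple[int, int]] = []
    pos_i = 0
    p = np.array([band_hi - wall_margin, band_hi - wall_margin])

    def emit_rest(duration):
        nonlocal pos_i
        n = max(1, int(round(duration * cfg.sample_rate)))
        parts.append(np.tile(p, (n, 1)))
        pos_i += n

    def leg(p0, p1, v):
        dist = float(np.hypot(*(p1 - p0)))
        n, v_adj = _quantized_steps(dist, v, dt, cfg.speed_min, cfg.speed_max)
        unit = (p1 - p0) / dist
        return p0 + unit * v_adj * dt * np.arange(1, n + 1)[:, None]

    emit_rest(float(rng.lognormal(mu, sigma)))
    while pos_i < n_total:
        to_center = rng.random() < cfg.p_enter_open
        in_center = bool(np.max(np.abs(p)) <= h)
        if in_center and not (rng.random() < cfg.p_return_closed):
            to_center = True  # may also wander within the center
        v = float(np.clip(rng.normal(cfg.speed_mean, cfg.speed_sd),
                          cfg.speed_min,
                          v_center_max if to_center else cfg.speed_max))
        if to_center:
            dest = rng.uniform(-center_r, center_r, size=2)
        else:
            dest = sample_surround()
        while float(np.hypot(*(dest - p))) < 0.7 * max(v, cfg.speed_min):
            dest = (rng.uniform(-center_r, center_r, size=2) if to_center
                    else sample_surround())
        waypoints = ([] if (to_center or in_center)
                     else _ring_waypoints(p, dest, corner))
        route, last = [], p
        for wp in waypoints + [dest]:
            if float(np.hypot(*(wp - last))) >= 1.0 or wp is dest:
                route.append(wp)
                last = wp
        seg = np.vstack([leg(a, b, v) for a, b in
                         zip([p] + route[:-1], route)])
        start = pos_i
        if start + len(seg) > n_total - 2:
            break
        parts.append(seg)
        pos_i += len(seg)
        bouts.append((start, pos_i - 1))
        p = seg[-1].copy()
        emit_rest(float(rng.lognormal(mu, sigma)))

    path = np.vstack(parts)[:n_total]
    if len(path) < n_total:
        path = np.vstack([path, np.tile(p, (n_total - len(path), 1))])
    return path, bouts


def generate_trajectory(cfg: BehaviorConfig,
                        rng=None) -> tuple[Trajectory, GroundTruth]:
    """Simulate one session; returns the trajectory and its ground truth."""
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    if cfg.arena.kind == "zero_maze":
        path, bouts = _gen_zero_maze(cfg, rng)
    else:
        path, bouts = _gen_open_field(cfg, rng)
    truth = _truth_from_path(path[:, 0], path[:, 1], bouts, cfg)
    x, y = path[:, 0].copy(), path[:, 1].copy()
    if cfg.rest_noise_sd > 0:
        rest = np.ones(len(x), dtype=bool)
        for i0, i1 in bouts:
            rest[i0:i1 + 1] = False
        x[rest] += rng.normal(0.0, cfg.rest_noise_sd, rest.sum())
        y[rest] += rng.normal(0.0, cfg.rest_noise_sd, rest.sum())
    dt = 1.0 / cfg.sample_rate
    traj = Trajectory(times=np.arange(len(x)) * dt, x=x, y=y,
                      sample_rate=cfg.sample_rate, arena=cfg.arena)
    return traj, truth


# ---------------------------------------------------------------------------
# photometry generation
# ---------------------------------------------------------------------------

def transient_kernel(cfg: PhotometryConfig, dt: float) -> np.ndarray:
    """Rise-decay transient kernel normalized to unit peak."""
    t = np.arange(0.0, cfg.kernel_support, dt)
    k = (1.0 - np.exp(-t / cfg.rise_tau)) * np.exp(-t / cfg.decay_tau)
    return k / k.max()


def generate_photometry(truth: GroundTruth, cfg: PhotometryConfig,
                        rng=None) -> tuple[RawPhotometry, GroundTruth]:
    """Synthesize the raw modulated voltage trace for a behavior session.

    Transients are triggered at the session's movement onsets (ground
    truth), each displaced by N(0, jitter_sd^2).  The demodulated-power
    envelope is baseline * bleach * (1 + sum of amplitude-scaled kernels);
    the emitted carrier amplitude is its square root, so the pipeline's
    df/f recovers the configured fractional amplitudes directly.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    duration = truth.session_length
    fs = cfg.sample_rate
    n = int(round(duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt

    onsets_nominal = np.asarray(truth.bout_start_times, dtype=float)
    jitter = (rng.normal(0.0, cfg.jitter_sd, len(onsets_nominal))
              if cfg.jitter_sd > 0 else np.zeros(len(onsets_nominal)))
    onsets = onsets_nominal + jitter
    if cfg.amplitude_cv > 0:
        sig = math.sqrt(math.log(1.0 + cfg.amplitude_cv ** 2))
        amps = cfg.amplitude * rng.lognormal(-sig ** 2 / 2.0, sig,
                                             len(onsets_nominal))
    else:
        amps = np.full(len(onsets_nominal), cfg.amplitude)

    kern = transient_kernel(cfg, dt)
    env = np.ones(n)
    for o, a in zip(onsets, amps):
        i = int(round(o * fs))
        if i >= n or i + len(kern) <= 0:
            continue
        lo, hi = max(i, 0), min(i + len(kern), n)
        env[lo:hi] += a * kern[lo - i:hi - i]
    power = cfg.baseline * np.exp(-t / cfg.bleach_tau) * np.maximum(env, 0.05)
    carrier = 0.5 * (1.0 + np.sin(2.0 * math.pi * cfg.carrier_freq * t))
    voltage = np.sqrt(power) * carrier
    if cfg.noise_sd > 0:
        voltage = voltage + rng.normal(0.0, cfg.noise_sd, n)

    truth.transient_onsets_nominal = onsets_nominal.tolist()
    truth.transient_onsets = onsets.tolist()
    truth.transient_amplitudes = amps.tolist()
    truth.photometry_config = cfg
    raw = RawPhotometry(times=t, voltage=voltage, sample_rate=fs,
                        carrier_freq=cfg.carrier_freq)
    return raw, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

KO_BEHAVIOR_OVERRIDES = dict(p_enter_open=0.12, bout_duration_median=1.1,
                             speed_mean=6.0)
KO_PHOTOMETRY_OVERRIDES = dict(jitter_sd=4.0)


def _truth_record(truth: GroundTruth) -> dict:
    return {
        "n_movements": truth.n_movements,
        "n_movements_into_open": truth.n_movements_into_open,
        "time_in_open_pct": round(truth.time_in_open_pct, 6),
        "bout_start_times": [round(v, 6) for v in truth.bout_start_times],
        "bout_end_times": [round(v, 6) for v in truth.bout_end_times],
        "n_entries": len(truth.entries),
        "transient_onsets": [round(v, 6) for v in truth.transient_onsets],
        "transient_amplitudes": [round(v, 8) for v in truth.transient_amplitudes],
        "session_length": truth.session_length,
        "sample_rate": truth.sample_rate,
    }


def generate_cohort(n_control: int, n_ko: int, outdir, seed: int = 0,
                    behavior: BehaviorConfig | None = None,
                    photometry_cfg: PhotometryConfig | None = None,
                    session_length: float = 600.0,
                    with_photometry: bool = True,
                    overwrite: bool = False) -> dict:
    """Write a control/KO-like cohort to disk and return the manifest.

    KO-like sessions lower the open-entry probability, shorten bouts, lower
    moving speed (the behavioral phenotype) and jitter transient onsets by
    4 s (the disorganized-activity phenotype).  Identical seeds reproduce
    byte-identical outputs.
    """
    if n_control < 1 or n_ko < 1:
        raise ValidationError("need at least one session per group")
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise ConfigError(f"{outdir} exists and is not empty (use overwrite=True)")
    outdir.mkdir(parents=True, exist_ok=True)

    if behavior is None:
        behavior = BehaviorConfig(arena=ArenaSpec.zero_maze())
    if photometry_cfg is None:
        photometry_cfg = PhotometryConfig()
    behavior = replace(behavior, session_length=session_length)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_control + n_ko)
    manifest = {"seed": seed, "sessions": []}
    groups = ["control"] * n_control + ["ko"] * n_ko
    for idx, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        bcfg = behavior if group == "control" else replace(
            behavior, **KO_BEHAVIOR_OVERRIDES)
        pcfg = photometry_cfg if group == "control" else replace(
            photometry_cfg, **KO_PHOTOMETRY_OVERRIDES)
        traj, truth = generate_trajectory(bcfg, rng=rng)
        sdir = outdir / f"session_{idx:02d}"
        sdir.mkdir(exist_ok=True)
        save_trajectory(traj, sdir / "trajectory.csv")
        files = {"trajectory": "trajectory.csv",
                 "ground_truth": "ground_truth.json"}
        if with_photometry:
            raw, truth = generate_photometry(truth, pcfg, rng=rng)
            save_photometry(raw, sdir / "photometry.txt")
            files["photometry"] = "photometry.txt"
        with open(sdir / "ground_truth.json", "w") as fh:
            json.dump(_truth_record(truth), fh, sort_keys=True, indent=1)
        manifest["sessions"].append({
            "id": f"session_{idx:02d}",
            "group": group,
            "files": files,
            "p_enter_open": bcfg.p_enter_open,
            "jitter_sd": pcfg.jitter_sd if with_photometry else None,
            "seed_entropy": int(child.entropy),
            "spawn_key": [int(k) for k in child.spawn_key],
        })
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
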