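"""Closed-loop transition-zone stimulation: scheduling, triggers, scoring.

The protocol stimulates as the mouse approaches the boundary between open
and closed arms: a trial starts once the mouse has remained in the
transition zone for at least 0.5 s, and is typed by approach direction
(closed->transition or open->transition) crossed with stimulation state
(stim / no-stim).  The default session is 40 trials, 10 per type, with
stim and no-stim interleaved pseudo-randomly within each direction.
Outcomes per trial: the next zone entered (retreat vs advance), the latency
from trigger to leaving the transition zone, and — when the outcome is the
closed arm — the duration of the subsequent closed-arm stay.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .arena import ZoneSeries, _runs
from .errors import ValidationError

DIRECTIONS = ("closed", "open")
STIM_DURATION = 2.0     # s
MIN_TRIGGER_DWELL = 0.5  # s
REFRACTORY = 2.0        # s between trials (prevents re-triggering mid-stim)


@dataclass
class TrialSchedule:
    """Ordered trial-type sequence with exact per-type counts."""

    sequence: list[tuple[str, bool]]  # (approach direction, stimulated)
    n_per_type: int
    seed: int

    def counts(self) -> dict:
        out: dict[tuple[str, bool], int] = {}
        for item in self.sequence:
            out[item] = out.get(item, 0) + 1
        return out

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Trigger:
    """A candidate trial start: 0.5 s of continuous transition dwell."""

    time: float
    direction: str        # previous non-transition zone
    run_start: int        # index of the first transition sample of the visit


@dataclass
class TrialRecord:
    """One scored closed-loop trial."""

    direction: str
    stim: bool
    trigger_time: float
    stim_onset: Optional[float]
    stim_duration: Optional[float]
    outcome: Optional[str]                 # next zone entered; None if censored
    latency_to_leave_transition: Optional[float]
    subsequent_closed_duration: Optional[float]
    censored: bool = False


def schedule_trials(n_per_type: int = 10, seed: int = 0) -> TrialSchedule:
    """Seeded pseudo-random interleaving with exact per-type counts."""
    if n_per_type < 1:
        raise ValidationError("n_per_type must be >= 1")
    types = [(d, s) for d in DIRECTIONS for s in (True, False)]
    seq = [t for t in types for _ in range(n_per_type)]
    rng = np.random.default_rng(seed)
    rng.shuffle(seq)
    return TrialSchedule(sequence=seq, n_per_type=n_per_type, seed=seed)


def detect_triggers(zones: ZoneSeries, min_dwell: float = MIN_TRIGGER_DWELL,
                    refractory: float = REFRACTORY) -> list[Trigger]:
    """Candidate triggers: the first sample at which continuous transition
    dwell reaches ``min_dwell``, with the approach direction taken from the
    previous non-transition zone.  At most one trigger per transition visit;
    triggers within ``refractory`` seconds of the previous one are skipped.
    Detection depends only on samples up to the trigger itself.
    """
    dt = zones.dt
    need = max(1, int(np.ceil(min_dwell / dt - 1e-9)))
    triggers: list[Trigger] = []
    prev_zone: Optional[str] = None
    last_time = -np.inf
    for s, e, lab in _runs(zones.zone):
        if lab == "transition":
            if prev_zone is not None and (e - s) >= need:
                t = float(zones.times[s + need - 1])
                if t - last_time >= refractory - 1e-9:
                    triggers.append(Trigger(time=t, direction=str(prev_zone),
                                            run_start=s))
                    last_time = t
        else:
            prev_zone = str(lab)
    return triggers


def score_trials(zones: ZoneSeries, schedule: TrialSchedule,
                 triggers: list[Trigger],
                 stim_duration: float = STIM_DURATION) -> list[TrialRecord]:
    """Match triggers to the schedule and score each resulting trial.

    Triggers are consumed in time order; each is matched to the next
    unconsumed schedule entry of the same approach direction (directions
    interleave independently because the approach direction is chosen by
    the mouse, while stim/no-stim is randomized within direction).
    """
    pending: dict[str, deque] = {d: deque() for d in DIRECTIONS}
    for d, stim in schedule.sequence:
        pending[d].append(stim)
    dt = zones.dt
    labels = zones.zone
    n = len(labels)
    records: list[TrialRecord] = []
    for trig in triggers:
        if trig.direction not in pending or not pending[trig.direction]:
            continue
        stim = pending[trig.direction].popleft()
        j0 = int(np.searchsorted(zones.times, trig.time + 1e-9))
        j = j0
        while j < n and labels[j] == "transition":
            j += 1
        if j >= n:
            records.append(TrialRecord(
                direction=trig.direction, stim=stim, trigger_time=trig.time,
                stim_onset=trig.time if stim else None,
                stim_duration=stim_duration if stim else None,
                outcome=None, latency_to_leave_transition=None,
                subsequent_closed_duration=None, censored=True))
            continue
        outcome = str(labels[j])
        latency = float(zones.times[j]) - trig.time
        closed_dur = None
        if outcome == "closed":
            k = j
            while k < n and labels[k] == "closed":
                k += 1
            closed_dur = (k - j) * dt
        records.append(TrialRecord(
            direction=trig.direction, stim=stim, trigger_time=trig.time,
            stim_onset=trig.time if stim else None,
            stim_duration=stim_duration if stim else None,
            outcome=outcome, latency_to_leave_transition=latency,
            subsequent_closed_duration=closed_dur, censored=False))
    return records


def summarize_trials(records: list[TrialRecord]) -> pd.DataFrame:
    """Per-type means: n trials, P(retreat to closed), latency, closed dwell.

    Censored trials are excluded from latency and dwell means.
    """
    rows = []
    for d in DIRECTIONS:
        for stim in (True, False):
            sel = [r for r in records if r.direction == d and r.stim == stim]
            done = [r for r in sel if not r.censored]
            lat = [r.latency_to_leave_transition for r in done]
            cd = [r.subsequent_closed_duration for r in done
                  if r.subsequent_closed_duration is not None]
            rows.append({
                "direction": d,
                "stim": stim,
                "n": len(sel),
                "n_censored": len(sel) - len(done),
                "p_closed": (np.mean([r.outcome == "closed" for r in done])
                             if done else np.nan),
                "mean_latency": float(np.mean(lat)) if lat else np.nan,
                "mean_closed_duration": float(np.mean(cd)) if cd else np.nan,
            })
    return pd.DataFrame(rows)
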