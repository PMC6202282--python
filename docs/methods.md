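# Methods

This note documents the models, conventions and numerical choices behind
`openarms`, and what the synthetic-data generator does and does not
emulate.

## Zone geometry

The zero maze is treated as a one-dimensional annulus: zones depend only
on the angular coordinate, never on radius, because the apparatus is a
7 cm-wide track and the zones are defined in degrees.  With closed arms
centered at 90° and 270° and a 30° transition arc, a point whose angular
distance to the nearest closed-arm center is `d` is classified closed if
`d ≤ 30°`, open if `d ≥ 60°`, and transition otherwise; each class covers
exactly 120°.  When transition zones are disabled (`transition_zones:
off`, the convention for analyses that report only open/closed occupancy)
the four arcs are split at their centers, giving 180° per class.  The
open-field center is interpreted as an *area* fraction: the concentric
square of side `side × √0.65 ≈ 0.806 × side`.  Both classifications are
exhaustive and mutually exclusive, so zone dwell times always sum to the
session length.

## Tracking and movement

Position files are resampled to a uniform grid (default 25 Hz, a typical
video rate that makes the 500 ms movement criterion an integral 13
frames) by linear interpolation.  Tracking dropouts up to 1 s are
interpolated; longer gaps abort with a data-quality error rather than
silently inventing a path.  Speed is the frame-to-frame displacement
times the sample rate, smoothed with a centered 200 ms moving average
(shrunken at the edges) because raw 25 Hz frame speed is noise-dominated;
both defaults are exposed in the config since tracking exports rarely
state them.

Movement bouts are maximal runs of samples with speed ≥ 2 cm/s
(inclusive) lasting ≥ 500 ms, where a run of n samples at rate fs counts
as n/fs seconds.  No gap tolerance is applied by default — a single
sub-threshold frame splits a bout — with `gap_tolerance` available for
sensitivity analyses.  A bout is attributed to a zone if it spends
≥ 500 ms there during the bout or lies entirely within the zone; a
boundary-crossing bout can therefore count toward several zones, and the
count of bouts attributed to both an open-class and a closed-class zone
is reported (`n_double_attributed`) so that convention is auditable.
"Speed while moving" is the distance-weighted mean speed over bout
samples (Σv²·dt / Σv·dt); the averaging convention is not standardized in
the literature, and the distance weighting makes it a property of the
path rather than of the time base.  The bout's `peak_time` is the
earliest sample achieving the maximum smoothed speed.

Zone *entries* are debounced with the same 500 ms rule: a run shorter
than `min_dwell` neither registers an entry nor terminates the previous
occupancy, mirroring the movement-attribution threshold.

## Photometry

The excitation LED is modulated at 80 Hz, so the photodetector voltage
carries the fluorescence on an 80 Hz carrier.  Demodulation computes a
short-time spectrogram (Hann window, default 0.5 s frames with 50%
overlap, per-frame mean removal) and integrates power over 79–81 Hz; at
the default frame length the 2 Hz band spans exactly one bin centered on
the carrier.  The frame length and step are configurable (any setting
with `window_length ≥ 1/bandwidth` resolves the band).

df/f uses a centered 1-minute rolling average f̄ around each point with
shrunken windows at the edges: `dff = (fₙ − f̄)/f̄`.  This makes the
result invariant to any global gain — the reason photometry signals are
normalized this way in the first place — and means transient amplitudes
are fractions of the demodulated band power.

Peri-event matrices resample df/f onto a −20…+10 s grid at 10 Hz around
each event (zone entry or movement onset); events whose window would
extend past the recording are dropped and counted.  Period means follow
the three-window convention: baseline [−15, −10] s, pre-movement
[−8, −3] s, movement [peak, peak+1] s.  The movement anchor is the bout's
speed peak by default, with `anchor="entry"` available because the two
conventions (movement peak vs. moment of entry) both appear in practice;
events whose peak-anchored window would leave the grid (very long, slow
bouts) are dropped from the movement average and logged.  Per-subject
period means are event averages; subjects are averaged before statistics.

`transient_amplitude` estimates the size of an event-locked transient as
the peak of the event-averaged trace referenced to the mean df/f just
before onset ([−3, −1] s).  The local reference matters: the 1-minute
rolling f̄ includes the session-average transient mass, which offsets the
whole df/f trace downward by roughly (event rate × transient integral ×
amplitude); the level immediately pre-onset shares that offset, so the
difference is a nearly unbiased amplitude estimate (≈ 0.95 of truth at
the default spectrogram smoothing), whereas the raw trace peak
underestimates by ~20% at typical movement rates.

## Closed-loop protocol

The scheduler emits `4 × n_per_type` trials (default 40) as a seeded
permutation with exact per-type counts; no run-length constraint is
imposed because none is standard.  A trigger fires at the first sample
where continuous transition-zone dwell reaches 0.5 s, with the approach
direction taken from the previous non-transition zone; one trigger per
visit, and a 2 s refractory period prevents re-triggering during the 2 s
stimulation.  Because the approach direction is chosen by the mouse while
stim/no-stim is randomized within direction, triggers are matched to the
next unconsumed schedule entry *of that direction*.  Latency is measured
from the trigger to the first sample outside the transition zone; the
subsequent closed-arm duration is the length of the closed run entered
after the trial; trials interrupted by the end of the session are marked
censored and excluded from latency means.

## Statistics

The avoidance regression is ordinary least squares of time-in-open on the
five behavioral features with an intercept; predictors are z-scored so
coefficients are comparable (R², F and p are scale-invariant).  Rank
deficiency raises an error naming the collinear predictors.  Partial
correlation residualizes both variables on the control by least squares
and correlates the residuals (df = n − 3).  The one-way repeated-measures
ANOVA across the three periods uses the standard subject/level/error
decomposition with no sphericity correction by default (Greenhouse-
Geisser via `correction="gg"`); pairwise period contrasts are paired
two-sided t-tests with Sidak adjustment (p' = 1 − (1 − p)³).  Paired
one-tailed t-tests return the one-sided p in the stated direction.
Subjects with missing periods are excluded listwise.  These are simple
closed forms implemented directly; the test suite cross-checks them
against pingouin on shared inputs, and calibrates their type-I error on
null simulations (0.05 ± 0.01 at 10,000 replicates).

## Synthetic data

The behavior model is deliberately semi-Markov rather than a learned
agent: rest epochs alternate with movement bouts, which is sufficient to
exercise every pipeline stage with known ground truth.

*Rest* epochs have lognormal durations with coefficient of variation 0.2
around a mean set by `bout_rate_per_min` (default 5 movements/min, i.e. a
movement roughly every 12 s — a realistic pacing for mice in these
arenas, where animals settle into fairly regular explore-pause cycles).
Rest positions jitter with 0.02 cm Gaussian tracking noise, far below the
2 cm/s threshold.  *Bouts* move at a per-bout speed drawn from
N(8, 1.5²) cm/s clipped to [3.5, 12]: on the maze, either a wander within
the current arm's core (lognormal duration, median 1.6 s) or a crossing
to the adjacent arm — into the open with probability `p_enter_open`
(default 0.35), back toward a closed arm with probability 0.75; in the
open field, straight segments to destinations sampled in the center
(probability `p_enter_open`) or in the wall-hugging surround frame,
routed around the center square via corner waypoints so that a
`p_enter_open = 0` session provably never enters the center.

All within-bout kinematics are quantized to the frame grid: per-bout
speeds are adjusted so each path is an integer number of `v·dt` steps and
wander reflections land on the step grid, so every frame displacement
within a scripted bout is exactly `v·dt ≥ 3.5 cm/s`.  This is what makes
bout counts, open-entry counts and time-in-open *exactly* recoverable by
the pipeline on noiseless sessions — the property the recovery tests
assert.  Session ground truth (bout windows, zone labels of the latent
noise-free path, entries, per-bout zone attributions) is recorded at
generation time.

Photometry synthesis triggers one transient per movement onset.  The
transient kernel is `(1 − e^{−t/0.2}) e^{−t/1.5}` normalized to unit
peak — a GCaMP6s-like 0.2 s rise and 1.5 s decay.  Amplitudes (default
0.06) are expressed as fractional changes of the *demodulated band
power*, the quantity df/f normalizes; the emitted carrier envelope is the
square root of the power envelope `bleach(t) × (1 + Σ aᵢK(t − oᵢ))`, so
the pipeline's df/f reads out the configured amplitude directly.  The
baseline bleaches exponentially (τ = 1800 s) and broadband Gaussian
voltage noise (sd 0.08, chosen to give ~2–3% per-frame df/f noise, a
typical SNR for 20–40 µW recordings) corrupts the trace.  KO-like
("disorganized") sessions keep the transient rate and amplitude fixed and
only jitter onsets with N(0, 4² s²) — isolating temporal disorganization
as the manipulated property.  With movement-locked transients the
movement-period df/f exceeds baseline robustly; with 4 s jitter the
transient mass is smeared over many seconds so that, at the default
pacing, the baseline window (12.5 s before an event, typically under the
previous movement's smeared transient) and the movement window see
comparable levels and the contrast collapses — reproducing the knockout
phenotype as a pipeline property.  Cohort generation additionally lowers
the KO group's `p_enter_open` (0.12), bout duration (median 1.1 s) and
speed (6 cm/s), emulating the behavioral phenotype, and is bit-for-bit
reproducible from its seed.

What the generator does *not* emulate: motion artifacts and hemodynamic
contamination (no isosbestic channel is modeled), body-pose ambiguity in
tracking, wall-rearing and grooming (rest is pure jitter), inter-mouse
variability in transient kinetics, and any learning across the session.
Passing recovery tests therefore demonstrates the correctness of the
pipeline's measurement conventions on signals of known structure, not
robustness to every artifact of real recordings.

## Problem sizes

Default test/verification scales, chosen as the package's own working
sizes: synthetic sessions of 240–600 s at 25 Hz tracking and 1 kHz
photometry; recovery checks over 8-session cohorts; the phenotype
contrast over 100 replicate cohorts of 8 control-like vs 8 KO-like mice;
statistical calibration on 10,000 null replicates; oracle-equivalence
checks on 1,000 random series per detector.
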