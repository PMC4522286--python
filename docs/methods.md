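# Methods

## Background and scope

The Finger Force Manipulandum (FFM) is a four-piston device that records the
force (N) exerted by the index, middle, ring and little finger independently
(strain-gauge sensors, nominal range 0–9 N, precision < 0.01 N). Four
visuo-motor tasks probe distinct components of manual dexterity:

1. **Force tracking** — force control: follow a trapezoid target (1.5 s linear
   ramp, 4 s hold, instantaneous commanded release, 2 s rest) at 1 N and
   2 N target levels, 24 trials in 4 blocks of 6.
2. **Sequential tapping** — motor sequencing: a five-tap sequence over the
   four digits, cued visually at 1 Hz for 10 trials (learning), then
   reproduced from memory for 5 trials (recall). Three sequences are
   predefined: A = 2-5-3-4-2, B = 4-3-5-2-4, C = 3-2-4-5-3 (2 = index,
   5 = little).
3. **Single-finger tapping** — timing: metronome-cued tapping at 1, 2 and
   3 Hz per finger (15 cued taps), each followed by an uncued phase of equal
   duration at the same intended rate.
4. **Multi-finger tapping** — finger individuation: cued one-finger (4 × 8),
   two-finger (6 × 5) and four-finger (× 2) tap combinations, 64 trials in
   pseudo-random order with the number of one→two and two→one finger
   transitions balanced to within one.

This package implements the task schedules, the trace analysis, normative
profiling, and a generative simulator; it does not talk to the hardware, and
it does not re-implement the repeated-measures ANOVA machinery used for
cohort-level inference (general statistics packages do that better).

Two printed task durations cannot be reconciled exactly with the printed
trial structure (24 × 7.5 s = 180 s for tracking; 15 × 5 s = 75 s for the
sequence task). Protocol durations are therefore always computed from the
schedule, never forced to a printed figure. The multi-finger inter-trial
interval is not printed; the default 4.375 s makes 64 trials span 280 s.

## Analysis pipeline

All analysis runs at 100 Hz. Recordings at higher rates are down-sampled
with a zero-phase 4th-order Butterworth low-pass at 0.45 × target rate
followed by linear interpolation onto the uniform target grid (the
anti-alias filter is this package's choice; the analysis rate is fixed).

**Tracking, per trial (N = 24):**

* RMSE between applied and commanded force, separately over the ramp and
  hold phases. The commanded trapezoid (not a rendered cursor) is the
  reference.
* Force onset and release onset as threshold crossings of the smoothed
  derivative dF/dt. The threshold is not specified by the source method; the
  default is ±1 N/s on a 50 ms moving-average-smoothed trace. Note a 1 N
  target ramp (slope 0.67 N/s) does not cross the default threshold: onset
  is then undefined for that trial, which is reported as missing rather
  than zero. Both values are configurable.
* Release duration: time from the first downward crossing of 75% of target
  to the first downward crossing of 25% of target after the hold, with
  sub-sample linear interpolation. If the force never falls below 25% of
  target within the rest window (incomplete relaxation), the measure is
  undefined for that trial.
* Hold mean and CV (sample SD / mean) over the central 3 s of the 4 s hold
  (first and last 500 ms trimmed).
* Baseline force: mean over the window 1500–500 ms before the next ramp
  onset; undefined for the first trial of a run.

Undefined values propagate as NaN and are excluded from per-subject means;
the number of trials used is reported per cell.

**Tap detection:** a tap is an above-0.5 N excursion of one channel; onset at
the upward crossing (sub-sample interpolated), peak at the local maximum,
amplitude at the peak. Above-threshold segments closer than a 100 ms
refractory interval merge. Both constants are configurable; the threshold is
the method's published definition, the refractory interval is this
package's choice.

**Sequential task:** the ordered finger string of taps in each 5 s trial
window is aligned to the target by longest common subsequence (LCS): correct
taps = LCS length, missing = 5 − LCS, extra = user taps − LCS, plus the
longest contiguous correct run (longest common substring). A trial is
correct only when the full string equals the target. The alignment algorithm
is not specified by the source method; LCS is the canonical choice. Error
taps per finger are the user taps left unaligned by one LCS traceback,
counted per tap (not per trial).

**Single-finger task:** per (finger, frequency, phase) condition, lead-finger
taps give the count, achieved rate (count / phase duration) and inter-tap
intervals. Non-lead taps within ±100 ms of a lead tap peak are *overflow*
taps (motor overflow); others are *unwanted* taps. The ±100 ms coincidence
window operationalises "at the same time" and is configurable. The rate
slope per finger is the OLS slope of achieved rate against target frequency
over 1/2/3 Hz, with rates pooled over cued and uncued phases (total taps /
total duration); slope 1 = veridical pacing, < 1 = slowed execution.

**Multi-finger task:** the response set of a trial is the set of fingers
with at least one tap peak in (cue, cue + window]; the window defaults to
the gap to the next cue, so windows never overlap and each tap belongs to
the nearest preceding cue. A trial is correct iff response = target.
Omission rate = omitted target-finger instances / target-finger instances;
unwanted extra-finger-taps (UEFT) are counted per event. Four-finger trials
are parsed but excluded from all rates. The error matrix has one row per
target combination (4 one-finger + 6 two-finger) and one column per finger;
a cell is the percentage of that combination's trials in which that finger
tapped erroneously; target-coincident cells are masked.

## Dexterity profile and norms

Six measures, all oriented larger-is-worse, as plotted per subject:

| measure | definition | unit |
|---|---|---|
| tracking_error | index-finger RMSE, ramp and hold pooled over all trials | N |
| release_duration | index-finger release duration, 1 N and 2 N pooled | s |
| one_minus_slope | 1 − rate slope (index finger, 1–3 Hz) | – |
| overflow_taps_1hz | overflow taps summed over the 1 Hz conditions | count |
| omission_rate | multi-finger omission rate | fraction |
| ueft_one_finger | UEFTs on one-finger trials | count |

Control norms are per-measure mean, sample SD, and threshold = mean + 2·SD
(exactly). A measure is flagged pathological when it *strictly* exceeds the
threshold. A subject who did not perform a task has the corresponding
measures and flags undefined. Clinically, a Moberg pick-up time above 18 s
on the affected hand is flagged.

The statistical surface is deliberately thin: a pooled-variance two-sample
t-test (Welch optional) for group contrasts and Spearman/Pearson
correlations (with R² for the measure-by-measure table) for clinical
relations. Pairs with missing values are dropped; zero-variance inputs give
undefined coefficients rather than errors.

## Synthetic data generator

No recordings for this device are publicly deposited, so the simulator is a
first-class module: it defines the study conditions under which every
analysis stage is validated, with exported ground truth.

*Tracking*: the lead finger follows the commanded trapezoid delayed by a
visuo-motor lag, rests at a constant baseline offset between trials, and
releases exponentially with time constant τ toward baseline (so the 75→25%
release duration is analytically τ·ln 3). White Gaussian sensor noise is
added; non-lead channels carry an enslaving-scaled copy of the lead trace.
No tremor band is modelled (hold-force CV showed no group difference and is
not a profile measure).

*Tapping*: each intended tap is a raised-cosine pulse (default peak 2 N —
the instructed tap force — width 200 ms) at the cue time, with optional
Gaussian timing jitter and log-normal amplitude variability. Cue trains
faster than the subject's maximum rate are thinned to that rate (minimum
inter-tap interval 1/max_rate), emulating rate saturation at 3 Hz. Cues are
omitted with a per-cue probability; extra taps on non-cued fingers are
injected with a per-cue probability. In uncued single-tap phases and recall
sequence trials the subject self-paces; the maintained tempo carries a
per-condition relative error (`tempo_drift_sd`), without which control
rate slopes would be artificially point-mass at 1 and mean+2SD thresholds
degenerate. Enslaving adds scaled copies of each pulse to the other
fingers; a coupled pulse appears in the ground truth as an event exactly
when its peak crosses the 0.5 N detection threshold, tying the generative
model to the analyzer's event definition.

Presets: `control_like` (low noise, τ = 0.1 s, near-zero baseline, max rate
5 Hz, near-diagonal enslaving, ~1% omissions/extras) and `paretic_like`
(noise 0.12 N, τ = 0.6 s, baseline 0.28 N, max rate 2.4 Hz, enslaving
decaying with anatomical distance — neighbours 0.35, distance 2: 0.24,
distance 3: 0.12 — 18% omissions, 12% extras). These values are this
package's own plausibility choices anchored to the qualitative contrasts
the method was designed to expose (elevated baseline, ~6× slower release,
rate saturation below 3 Hz, a neighbourhood gradient of error taps); they
are *not* estimates of any real cohort, and cohort-level numbers obtained
from them must not be read as reproductions of published group values.

Cohorts draw a severity in [0, 1] per subject (controls U(0, 0.08),
patients U(0.4, 1.0)), interpolate all parameters linearly between the two
presets, and add a per-subject log-normal draw (relative sd 0.08) around
the interpolated values, so control measures have realistic unimodal
variability for mean+2SD norming. Synthetic clinical scores (ARAT, Moberg,
grip) degrade linearly with severity plus noise, giving the correlation
operations signal by construction.

**What passing tests show and do not show.** Generator/analyzer closure
(zero-noise settings recover analytic values; detection precision/recall 1;
scoring equals brute-force tallies) validates the analysis code, and preset
separation validates the direction of every profile measure. None of this
validates the method against real patient data: the simulator has no
biomechanics, no learning dynamics within the sequence task, no tremor, and
its parameter values are assumptions.

## Numerical choices and problem sizes

* Crossing times (release duration, tap onsets) use linear interpolation
  between samples; everything else is sample-aligned at 100 Hz.
* Ties/degenerate inputs: empty analysis windows raise; per-trial measures
  that cannot be computed are NaN, never zero; rate slope needs at least two
  distinct frequencies; norms need at least two defined control values.
* The preset-separation suite runs 200 seeds per preset on reduced-size
  protocols (6 tracking trials, 8 cued taps per condition, 16 + 18 + 1-trial
  multi task), a package choice that keeps the Monte-Carlo suite small while
  the claims under test concern preset means, not protocol sizes. The
  profiling suite uses full-size protocols on a 30-control / 24-patient
  cohort with norms from 10 controls and 20 held-out controls.
* Seeded rejection sampling for the multi-task transition balance retries up
  to 10,000 permutations, then warns and keeps the last candidate (any
  permutation is automatically within one of balance except in tiny
  degenerate cases).

## Known limitations

* Sequence trials are scored within fixed 5 s windows; recall trials
  produced "as quickly as possible" are still windowed at the cue-rate
  spacing.
* Ground truth for overlapping enslaved pulses (two simultaneous lead
  fingers leaking onto the same third finger) lists each contribution
  separately and may undercount threshold crossings of their sum; closure
  tests avoid this regime.
* The onset-detection default (1 N/s) leaves force onset undefined on 1 N
  ramps; onset timing showed no group difference and is not a profile
  measure, but users studying it should lower the threshold.
* Error bars on the error matrix (across-subject SDs) are not computed
  within a single session; aggregate across sessions for that.
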