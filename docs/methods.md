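# Methods

`nocturne` implements an end-to-end analysis stack for in-home monitoring of
nocturnal enuresis (NE, bedwetting during sleep): a synthetic night
generator with planted ground truth, windowed feature engineering over three
sensor modalities, a linear probability-label model, five wetting-moment
estimators, day-level evaluation, and the data-collection supervisor state
machine. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data does and does not establish.

## Sensor model

A night is a set of aligned streams: pelvic bioimpedance (BI) and a
moisture-sensor resistance at 250 Hz, heartbeat (R-peak) times derived from
a 250 Hz ECG, and 3-axis accelerometer + gyroscope on each ankle at 100 Hz.
All analysis operates on non-overlapping, contiguous 30-second windows
indexed from 0, half-open `[t, t+30)`, with times in seconds from collection
start. Gaps (NaN runs) up to 10 s in dense channels are linearly
interpolated between their endpoints; windows touched by longer gaps are
flagged missing and excluded downstream rather than imputed. The 10-s limit
is a declared default (device dropout behaviour gives no principled rule).

## Bladder-volume features

Urine conducts, so impedance measured near the pelvis falls as the bladder
fills. Raw BI is confounded by per-subject baseline offsets, posture
step-changes, and large movement artifacts. The feature family isolates the
slow filling trend:

* **BID** — cumulative sum of successive BI differences with any single-step
  difference exceeding a bound `D_upper` clipped to zero. Artifacts enter
  and leave through steps larger than `D_upper` and cancel out; the filling
  drift passes through. `BID(T) = Σ_{i≤T} D_i` with
  `D_i = BI_i − BI_{i−1}` if `|BI_i − BI_{i−1}| ≤ D_upper`, else 0.
* **BID_decrease** — the same accumulation restricted to bounded decreases
  (`0 ≤ BI_{i−1} − BI_i ≤ D_upper`); every contribution is ≤ 0, so the
  series is non-increasing and emphasizes the filling direction.
* **DBID** — lag-1 first difference of the per-window BID series: the speed
  of bladder-volume change. "Delta of BID" admits several readings; the
  lag-1 window difference is the simplest and is configurable.
* **Clt** (clutter) — the window's background level, operationalized as the
  sample median (robust to artifact spikes). The term is borrowed from
  radar signal processing; no precise definition exists upstream, so the
  median is a declared choice.
* **BI** (window representative) — mean of window samples within `D_upper`
  of the window median, i.e. an artifact-trimmed mean.

`D_upper` defaults to 5× the median absolute successive difference of the
night's opening 5 minutes (assumed artifact-light), with a 1e-12 floor so a
noiseless series still clips its artifacts. Per-window BID/BID_decrease
accumulate over the whole night's sample-level difference series up to each
window's last sample, so windows carry the night-long trend. NaN samples
void the two differences touching them (contributing 0).

Two identities anchor the implementation and are tested exactly: with
`D_upper` larger than every step, BID telescopes to `BI_T − BI_0`; and a
spike whose entry and exit steps both exceed `D_upper` leaves BID unchanged.

## Heart-rate-variability features

Beat times → NN intervals (ms) gated to [300, 2000] ms (covers pediatric
sleep rates; configurable). Per window, nine features: HR max/mean/min/std
computed from instantaneous per-interval rates (60000/NN, the HRV
convention), `nni_20`/`nni_50` counts of absolute successive-interval
differences over 20/50 ms, their percentages `pnni_20`/`pnni_50` with the
number of successive differences as denominator, and `range_nn = max − min`
interval. Windows with fewer than two intervals are flagged missing, not
erred. R-peak detection (raw-ECG mode only) band-passes 5–40 Hz, picks
peaks above 4 robust SDs with a 300 ms refractory, and refines each to the
local raw-signal maximum; the simulator emits beat times directly by
default because the pipeline only consumes intervals.

## Limb movements and the PLMS index

Detection runs on the high-pass-filtered (0.5 Hz) acceleration norm: a
0.1-s moving-RMS envelope must exceed the quiet-night floor (envelope
median) plus 8 robust SDs; spans separated by < 0.5 s merge; candidates
must last 0.5–10 s. Periodicity follows AASM-style scoring: only movements
in a series of ≥ 4 with successive onsets 5–90 s apart qualify. Both
ankles are pooled, with bilateral events within 0.5 s counted once. The
PLMS index is qualifying movements per hour of the total collection time
(estimated sleep time is not available to the pipeline), and an index ≥ 5/h
is read as a PLMS disorder. The movement magnitude feature is the mean
filtered-acceleration norm per window; the angle-difference trend is the
least-squares slope of the integrated dominant-axis gyroscope rate,
expressed per window; motion counters are detected onsets per window per
side.

## Probability labels and the alarm rule

Wetting happens at most once or twice a night, so discrete window classes
would be hopelessly imbalanced; instead each window gets a continuous
target from a linear-in-time model evaluated at window end times. Enuretic
night: probability rises from 0 at collection start to exactly 1.0 at the
wetting moment; windows starting after the moment are excluded from
supervised targets (collection effectively ends at the event). Dry night:
0 at start to 0.70 at collection end — clinical advice puts end-of-night
risk on a dry night at 70%. The zero anchor at collection start is a
declared choice (the upstream description is asymptotic); it is
configurable. The alarm rule fires when probability is strictly greater
than 0.85; under the linear model a dry night can never alarm, and an
enuretic night first alarms at `0.85 × ne_moment`.

## Estimators

All estimators consume blocks of 20 consecutive windows (10 min) slid by
one window; a 960-window night yields 941 blocks. Four rule-based
estimators AND together per-modality conditions — RE_B: bladder only;
RE_BL: + limb movement; RE_BH: + heart rate; RE_ALL: all three:

* bladder: cumulative BID at the block end ≤ `theta_bid`. Default
  calibration: 60% of the most-negative BID over a calibration set.
* heart rate: block mean HR ≥ night baseline + `theta_hr` (default 5 bpm);
  the baseline is the mean over the opening hour or first quarter of the
  night, whichever is shorter.
* limb movement: ≥ `theta_lm` (default 1) detected movements in the block.

Because condition sets nest, positive-block sets nest:
RE_ALL ⊆ RE_BH ⊆ RE_B and RE_ALL ⊆ RE_BL ⊆ RE_B — asserted on every
simulated cohort.

The deep estimator (DE) is a convolutional–biLSTM–attention regressor:
three branch convolutions (one per modality, kernels spanning the branch's
full feature dimension × 3 time steps, 6 channels, tanh), per-step
concatenation, a bi-directional LSTM (hidden 12 per direction), additive
attention over time steps, and a sigmoid head — ~3.7k parameters, well
under the 1e5 budget. Training minimizes MSE against the linear targets at
each block's last window with Adam (lr 0.02, batch 256), split by night
(never by block, to avoid leakage), deterministic given the seed. The
network runs on a small vectorized reverse-mode autodiff engine
(`nocturne.nnet`) written for this package and checked against numerical
gradients; it is a deliberate, minimal implementation, not a general
framework. Day-level reduction: a night is predicted enuretic if any block
is positive (rules) or any block probability exceeds 0.85 (DE);
configurable to ≥ k blocks. Undefined precision/recall (zero denominators)
are reported as `None`, never NaN.

## Synthetic nights

The real cohorts (four children monitored at home for ~8 weeks; thirty
children in a one-time in-hospital saline-filling study) cannot be
redistributed, so the generator emulates the statistical structure the
pipeline consumes, with planted ground truth carried on every night.
Defaults mirror the monitored cohort where its summary statistics are
published; everything else is a realistic declared choice:

| parameter | default | basis |
|---|---|---|
| nights enuretic | 78/173 ≈ 0.451 | cohort totals |
| pre-wetting HR ramp on enuretic nights | 23/78 ≈ 0.295 | cohort count |
| PLMS index target | 15.59 /h | cohort mean |
| sleep duration | 8 h | cohort protocol |
| BI/moisture rate; motion rate | 250 Hz; 100 Hz | device spec |
| BI baseline | U(150, 450) Ω per subject | plausible two-electrode pelvic BI |
| fill drift | −6 Ω/h | gives overnight BID ≈ −48 Ω, same order as the artifact scale |
| BI noise | smooth, SD 0.3 Ω, 30-s knots | hardware noise at 4 ms spacing is strongly correlated; iid sample noise would make decrease-accumulation diverge |
| posture steps | 1.5/h, ±(2–6) Ω persistent | baseline shifts of either sign |
| artifacts | 6/h, 0.5–3 s, ±(40–80) Ω | "huge" movement excursions, both edges clipped |
| HR | 85 bpm baseline, ±1.5 bpm slow wander, 25 ms beat jitter | pediatric sleep |
| HR ramp | +8 bpm over the 10 min before wetting | detectable but physiologic |
| PLM series | length 4–8, onsets 10–60 s apart, bursts 0.5–4 s, 0.4 g | within AASM-style bounds |
| moisture | 10 kΩ dry → 300 Ω wet at the moment, SD 50 Ω | sensor-like step |
| wetting moment | uniform over the last 70% of the night | declared (no published distribution) |

The in-series movement count per night is Poisson with mean
`target × hours`; when a draw is smaller than one series, a minimal series
is planted with matching probability so the expected rate is preserved.
Saline-filling sessions fill 0 → capacity linearly over 10 min with BI
falling at −0.08 Ω/cc plus the same noise/artifact model. Determinism:
every night derives from `SeedSequence(seed, night_index)`; identical
inputs give bit-identical streams.

What the generator does **not** model: sleep stages, real artifact
morphology, circadian HR architecture, inter-night subject correlation, or
any coupling between movements and BI artifacts. Passing tests therefore
establish that the pipeline recovers the structure it is designed for —
not clinical performance on real patients; the published headline results
on the real cohorts are not reproducible without those data.

## Pre-wetting heart-rate-rise detection

A night is flagged "HR rose before wetting" when the mean windowed HR over
the 5 min before the moment exceeds a *local* baseline (the 20 min ending
10 min before the moment, i.e. just before any plausible ramp) by more than
3 bpm — half the expected pre-window elevation for the default ramp shape.
The local baseline cancels slow overnight HR wander, which a
start-of-night baseline does not; the detector falls back to the opening
5 minutes when the moment comes too early. On simulated cohorts this
separates ramped from unramped nights with no false positives.

## Collection supervisor

A finite state machine over {START, NORMAL, END, DELAY, PROBLEM,
TERMINATED}: activation moves START→NORMAL; faults move NORMAL→DELAY; a
cleared fault returns to NORMAL (a recovery edge that is implied upstream
but never named — added here); a delay maintained strictly longer than
600 s escalates to PROBLEM on the next tick; re-initiation success returns
to NORMAL, failure uploads and enters the absorbing TERMINATED state
(distinct from the ordinary END, which the upstream description
conflates). NORMAL re-evaluates every 3 s and uploads continuously, so the
un-uploaded span at any exit is bounded by one tick. The machine is total
over the documented pairs; undocumented (state, event) pairs raise, never
silently self-loop. PROBLEM retries once by default.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale cohorts chosen as the package's own
benchmark sizes: 20 one-hour nights for PLMS recovery, 100 45-minute
enuretic nights for ramp-fraction recovery, 20 nights for wetting-moment
detection, 30 saline sessions for the correlation study, and a 40-night
strongly separable cohort (steeper filling, guaranteed ramp, denser
movement series on enuretic nights; 8 epochs) for the end-to-end deep
benchmark. Full 8-hour nights at full rates are supported and used in
spot checks. Tolerances: brute-force feature agreement is exact (1e-12);
PLMS recovery ±15% of target; ramp fraction within binomial 3σ; wetting
moment within ±30 s. Ties and degenerate inputs: empty windows flag
missing rather than raise wherever a night can still be used; zero-variance
series are rejected by the correlation routines with explicit errors.

## Known limitations

* BID_decrease is meaningful only because the simulated BI noise is smooth;
  on hardware with appreciable white noise at 250 Hz the feature would need
  pre-smoothing or a deadband.
* The PLMS index uses total collection time as denominator; with actual
  sleep-time scoring the index would run higher.
* Probability labels are a modelling device, not calibrated probabilities;
  there is no ground truth against which to calibrate them.
* The deep estimator's benchmark cohort is deliberately separable; its
  accuracy there is an implementation sanity bound, not a clinical claim.
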