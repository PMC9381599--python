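# Methods

This note documents the models, conventions and design choices behind the
package: what each pipeline stage computes, which parameters matter, what
the synthetic cohort does and does not emulate, and the numerical decisions
that make the behaviour reproducible.

## Sensor streams and calendar conventions

Three contactless streams are modelled, matching a typical zero-interaction
deployment for community-dwelling older adults:

* **PIR activity** — per-room binary on/off epochs on a strict 2-s grid
  (0.5 Hz), for the five essential rooms (entrance, bathroom, bedroom,
  living room, kitchen) plus an optional `other`. Device outages are
  represented in memory by an `observed` mask; on disk, unobserved epochs
  are simply absent (the CSV is run-length encoded).
* **Door events** — open/close events for the entrance and fridge doors.
  Reed switches drop events in practice, so streams are normalized on read:
  exact duplicates are removed and a repeated state triggers insertion of
  the complementary event at the midpoint of the offending interval
  (logged). Downstream outing detection requires this alternation.
* **Bed sensor** — one record per in-bed period: heart rate, respiration
  rate, in-bed activity and sleep stage (awake/REM/deep/light) on a shared
  4-s grid (0.25 Hz), plus toss-and-turn timestamps and bed-exit intervals.

All timestamps are timezone-aware. Days are local midnight-to-midnight
(23/25-h days across DST are accepted); all windows are half-open
`[start, end)` so no observation is counted twice. Nights are anchored
noon-to-noon to the evening's calendar date — the standard actigraphy
convention — and when several in-bed periods anchor to one date, the
longest is the main night and shorter ones are treated as naps and
excluded.

**Day validity** (configurable, `ValidityCriteria`): a day counts for the
PIR/door system when the union of essential-room PIR coverage spans ≥ 20 h
and the union activity signal changed state at least once; it counts for
the bed system when the anchored night exists with ≥ 3 h of non-missing
stage samples. These defaults stand in for deployment-specific inclusion
rules and are deliberately exposed in configuration.

## Base measures

The measure registry declares 53 daily/nightly base measures and 4
per-segment measures, covering the families of interest in passive
monitoring: room-level activity and transitions, outings, fridge use,
door-event times of day, sleep architecture, bed exits and toss-turns,
in-bed activity, nocturnal heart rate and respiration, spectral content of
the night channels, and circadian rhythmicity. The registry is extensible
at runtime (`register_measure`); duplicate ids are rejected. Conventions
that needed pinning:

* **Room transitions** count changes of the most-recently-active room
  across the day's active epochs.
* **Activity fragmentation** is the number of active↔inactive alternations
  of the union activity signal divided by total active minutes, a
  duration-invariant restlessness index.
* **Room entropy** is the Shannon entropy (natural log) of the distribution
  of active epochs over the five essential rooms; range [0, ln 5].
* **Outings** are pairs of consecutive entrance-door events enclosing ≥ 5
  min (configurable) of complete interior PIR silence; shorter quiet gaps
  are door answering, not outings.
* **Door time-of-day** measures report first/median/last event times in
  decimal hours. `*_tod_middle` is the *median* event time.
* **Sleep onset/offset** use a noon-anchored clock (hours + 24 when past
  midnight, range [12, 36)) so onsets straddling midnight remain 1 h apart
  rather than 23 h, which keeps segment-level quantiles meaningful.
* **WASO** counts awake minutes strictly between sleep onset (first asleep
  sample) and final awakening.
* **Heart-rate dipping** is a within-night proxy: (B − T)/B with B the mean
  HR over the first 30 min in bed and T the minimum 10-min rolling-mean HR.
  The bed sensor records no daytime HR, so the classical day/night dipping
  ratio is not computable; baseline and rolling windows are configurable.
* **Spectral measures** use Welch periodograms (Hann window, 256-sample
  segments, 50% overlap) after linear interpolation of gaps ≤ 60 s; longer
  gaps split the channel and per-chunk estimates are averaged with
  chunk-length weights. Band powers over (0–0.01], (0.01–0.04],
  (0.04–0.125] Hz are reported as fractions of total (DC-excluded) power;
  spectral entropy is normalised to [0, 1]. A constant channel has zero
  power and MISSING fractions/entropy.
* **Cosinor** fits y(t) = M + A·cos(2πt/24 − φ) by linear least squares on
  the 10-min-binned union activity signal of a whole bi-weekly segment,
  giving MESOR, amplitude, acrophase (hours, [0, 24), on the local clock)
  and R². Zero-variance signals yield amplitude 0 and MISSING acrophase.

## Bi-weekly aggregation

Daily values are aggregated over non-overlapping 14-day segments that start
at the participant's first recorded day (recording-relative, not
calendar-aligned, since enrolment dates roll). A trailing partial segment
is dropped. For each base measure with ≥ 10 valid days in a segment
(`min_days`, configurable), the summary-statistic set
{q10, q25, q50, q75, q90, iqr, mean, coefvar, kr3, sk3} is emitted as
`<stat>_<base_id>`; otherwise every derivate is MISSING. MISSING propagates
— it is never imputed at this layer, because the downstream classifier
handles missing values natively.

Statistic definitions pinned for bit-stable tests:

* Quantiles: linear interpolation between closest order statistics.
* `coefvar`: SD (n−1 denominator) / mean; MISSING when |mean| < 1e-12.
* `sk3` (robust skewness, Groeneveld–Meeden form):
  (mean − median) / mean(|x − median|). A constant sample is exactly
  symmetric, so 0/0 here is defined as 0; a vanishing denominator with a
  non-vanishing numerator is MISSING. Requires ≥ 3 values.
* `kr3` (robust kurtosis, Hogg form):
  (Ū.05 − L̄.05)/(Ū.50 − L̄.50) − 2.59, where Ū_α/L̄_α are means of the
  upper/lower α-fraction of order statistics with fractional weighting of
  the boundary order statistic. The centering constant 2.59 is the
  population value of the ratio for a standard normal
  (φ(z.95)/0.05 ÷ φ(0)/0.5 = 4.1254/1.5958 ≈ 2.585), so kr3 ≈ 0 on normal
  samples. It needs ≥ 20 present values for the 5% tail means to be
  meaningful — which a 14-day segment never reaches, so `kr3_*` exhaust
  columns are structurally MISSING with the default statset. They are kept
  for registry/statset completeness; the classifier ignores all-missing
  columns. Shorter-horizon users can lower `min_n` deliberately.

Vector dimensionality is a pure function of (registry, statset): with the
built-in registry, 53 × 10 + 4 = 534 columns, identical across
participants and segments.

## Synthetic cohort

The generator produces format-conformant streams with controllable
phenotype signal; it emulates *statistical structure*, not sensor physics:

* Occupancy is semi-Markov: exponential dwells with per-room means (scaled
  so expected transitions/day match `transition_rate`), next room sampled
  ∝ dwell mass. Motion within an occupied room is duty-cycled at the
  minute scale (`activity_duty` = 0.35).
* Outings pause occupancy and emit entrance open/close pairs at departure
  and return with brief entrance PIR bursts; fridge events are Poisson over
  at-home waking time with kitchen PIR bursts.
* Nights: onset ~ N(22:30, 45 min), duration ~ N(7.5 h, 45 min). HR follows
  a plateau–ramp–trough–ramp profile with per-night dip fraction ~
  N(hr_dip_frac, hr_dip_frac_sd) truncated to [0, 1] plus AR(1) noise
  (coefficient 0.9 at 4-s steps — slow physiological wander); stages come
  from a 4-state Markov chain sampled run-wise; toss-turns and bed exits
  are Poisson, with bed exits masking all channels.
* Phenotype effects: per-assessment latent severities (cases ~ U(0.7, 1),
  controls ~ U(0, 0.3)) shift routine parameters via additive or
  multiplicative effect maps. Default directions: frailty/depression/MCI
  reduce transitions, fridge use and outings and lengthen sleep; fall risk
  raises in-bed activity and bed exits; MCI additionally inflates
  night-to-night dipping variability and sleep-onset variability.
  Magnitudes are free configuration — the defaults are deliberately strong
  enough for closed-loop recovery tests.
* Assessment scores are drawn uniformly from the correct side of the
  standard cut-offs (TUG ≥ 12 s, POMA < 19, EFS > 5, GDS ≥ 5, MoCA < 23),
  with `label_noise` flipping sides at a configurable rate; case counts are
  exact by construction. Demographics (age ~ N(84, 6) clipped to [70, 99],
  sex, cohort) are independent of phenotype by default, so demographics-only
  classifiers should sit near chance.
* Outages are Poisson with exponential durations per affected system
  (PIR+door fail together; the bed sensor separately), deleting observed
  epochs, door events and whole nights.

Simulated cohorts default to UTC so every day has exactly 43 200 PIR
epochs; DST handling is exercised separately with real-timezone fixtures.
What the simulator does **not** model: multi-resident homes, visitors,
pets, sensor cross-talk, circadian phase drift, seasonal behaviour change,
or any raw waveform physics. Pipeline tests passing on synthetic cohorts
therefore demonstrate correctness of the *computation*, not clinical
validity on real homes.

## Digital clinical outcome assessments

Each assessment's dataset joins exhaust vectors to demographics (age
numeric, sex/cohort binary-encoded) and one dichotomized label per
participant (multiple scores are averaged before the cut-off). Segments
additionally carry the temporally closest assessment (ties → earlier).
Segment validity requires the missing fraction within *each* sensor-system
block (PIR+door vs bed) to be < 30%; the looser "≥ 30% of each block
present" variant is available as a config option. A cohort-bias screen
flags measures whose single-feature ranking AUC for cohort membership
reaches 0.95 (symmetric, missing excluded), plus any manual exclusions.

Evaluation mirrors small-n digital-biomarker practice: 100 iterations of
participant-level label-stratified 70/30 splits (all segments of a
participant on one side — asserted every iteration); per iteration, an
XGBoost classifier (`tree_method="hist"`, native NaN handling) is tuned by
random search (50 trials by default) over {trees 50–500, depth 2–8,
learning rate log-uniform [0.01, 0.3], subsample [0.5, 1], colsample
[0.3, 1], min child weight 1–10} with inner participant-level stratified
3-fold CV scored by segment-level ROC AUC, then refit on the full training
split. Segments are the training rows (labels broadcast); test-segment
probabilities are soft-voted (arithmetic mean) into one score per
participant before ROC AUC and PrAUC (positive class = negative health
outcome) are computed. Iteration summaries are reported as mean ± 1.96·SE
(a percentile option exists). Inner-CV folds clamp to the minority-class
count; with < 2 participants per class per side the iteration is resampled
(logged) and ultimately rejected.

## Explainability

SHAP values are exact TreeSHAP contributions in log-odds units, computed
through XGBoost's native `pred_contribs` predictor. Global importance of a
measure is the sum over iterations of the mean |SHAP| on that iteration's
test samples — additive over disjoint iteration sets and
permutation-invariant, with dense descending ranks. Beeswarm data come
from a *separate* single model fit on the whole dataset with fixed
hyperparameters (search-space midpoints by default), exporting per-sample
SHAP for the top-9 measures plus the row-summed remainder; per-row sums
plus the base value reproduce the model margin exactly (local accuracy).
The two rankings can differ slightly by construction; the global one is
authoritative. The group-averaged exhaust export chains per-participant
means over segments → per-measure z-normalisation across participants
(population SD) → outcome-group means.

## Problem sizes in the shipped tests

The test suite runs the full closed loop at n = 40 participants × 180 days
with 20 evaluation iterations and 10 search trials; the acceptance script
uses the same cohort with 10 iterations per scenario. Statistic
calibrations run at n = 10⁵. These sizes keep ≥ 12 bi-weekly segments per
participant and stable AUC estimates while completing comfortably on a
single CPU. The null-cohort distribution check runs at 28 days since the
property is horizon-free. Two pure-speed choices in the classifier factory
— 16 histogram bins and up-front removal of structurally all-missing
feature columns — do not change what the model can express at these data
sizes.

## Known limitations

* The built-in registry is representative, not exhaustive; real
  deployments will extend it (the registry API exists for that).
* `sleep_onset/offset_tod` assume a single nightly sleep period; polyphasic
  sleepers are summarised by their main night only.
* The outing detector cannot distinguish a resident leaving from a fully
  motionless home (e.g. sleeping in an unsensed room).
* Multi-resident homes are out of scope throughout; many measures are
  ill-defined when more than one person generates motion.
* kr3 derivates are structurally MISSING at 14-day segments (see above).
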