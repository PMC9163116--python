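# Methods

## The model

`tas` quantifies how unusual a stretch of a person's day is, using only
minimally processed smartphone sensor streams. For one participant and one
sensor, the preprocessed time series `T = (t_1, ..., t_n)` is partitioned by
a **temporal rule** `R` — day-of-week, weekday-vs-weekend, or a single
all-days group — into a list `L` of groups. Within each group `G`, the data
is sliced into subseries spanning a **resolution** `tau` hours of local
clock time (`tau` must divide 24; `tau = 24` gives whole-day segments,
`tau = 1` hourly ones). Members of a group share a temporal characteristic
("Tuesdays", "weekend mornings"), so they are comparable: the method
computes the `l x l` symmetric matrix of pairwise trajectory distances over
the `l` segments of `G`, and scores each segment by the mean (or median) of
its off-diagonal row — the **temporally-aligned similarity (TAS) score**.
A high score means the segment deviates from its own group, which is the
unit of anomaly here: a deviation from *this person's* routine, not from a
population norm.

Three distances are implemented:

- **DTW.** Accumulated cost `D(i,j) = min(D(i-1,j), D(i,j-1), D(i-1,j-1)) +
  d(i,j)` with `D(0,0) = 0` and an infinite first row and column (the
  standard boundary convention consistent with the warp-path length bound
  `max(m,n) <= K < m+n`). The local cost is Euclidean: absolute difference
  for scalar series, planar distance on (lat, lon) degree pairs for GPS
  (great-circle meters available via `gps_metric="haversine"`). The distance
  equals the summed local cost along the optimal monotone path, which is
  recovered by backtracking (diagonal preferred on ties).
- **epsilon-LCSS.** `L(i,j) = 1 + L(i-1,j-1)` when the elements match
  (`|a_i - b_j| < epsilon`, strict; Euclidean norm for 2-D points;
  `epsilon = 0` means exact equality), else `max(L(i-1,j), L(i,j-1))`, with
  zero boundaries. The distance is the normalized `(m + n - 2z)/(m + n)`,
  which is 0 for identical and 1 for disjoint sequences. The variant
  `(m + n + 2z)/(m + n)` is available as `formula="as_printed"`; it grows
  with similarity and therefore is not used downstream.
- **Lock-step.** Mean pointwise Euclidean distance after truncation to the
  common length — a deliberately alignment-free third comparison.

Sensor-specific preprocessing keeps the inputs close to raw:

- **GPS** — round lat/lon to 3 decimal places (~110 m cells in latitude),
  then keep the modal rounded pair per 30-s interval. No interpolation:
  empty intervals stay empty, missing data stays missing.
- **Accelerometer** — jerk, the per-second rate of change of the
  acceleration magnitude `|a| = sqrt(x^2+y^2+z^2)`, one value per sample
  after the first. Jerk responds to movement of the device while discarding
  orientation, and deliberately supports no activity recognition.
- **Screen** — the off-bout duration (seconds since the screen last turned
  off) attached to each screen-on event.

Downstream, daily scores populate a calendar table (one cell per date;
hourly scores are averaged within a date when `tau < 24`), hourly scores a
24-slot clock profile with ranks, and anomalies are flagged per group by a
Tukey fence (`score > Q3 + k * IQR`, `k = 1.5`) or a rank-based quantile
rule. Daily scores can be correlated (Pearson, two-sided) with daily survey
scores, pooled over participant-days or averaged per participant.
Hierarchical clustering (scipy linkage on the precomputed matrix) and
DBA-style barycenter averaging provide routine clusters and a personal
baseline trajectory.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| GPS downsample interval | 30 | s | noise suppression + dimensionality; the mode over each half-open bin is robust to jitter |
| GPS rounding | 3 | decimal places | ~110 m cells; positions become privacy-preserving grid cells |
| jerk gap threshold | 5 | s | pairs spanning a longer gap are dropped; a rate across a data gap is an artifact, not a movement |
| `jerk_per_second` | true | — | "rate of change" read as a per-second rate; the per-sample difference is a config switch |
| `tau` | 24 | h | whole-day comparison; must divide 24 so slots tile the day |
| `min_points` | 2 | points | the minimum for any pairwise alignment; smaller segments are dropped and counted |
| LCSS `epsilon` | 0.001 deg / 0.1 g s^-1 / 60 s | per kind | one quantization unit of each representation |
| Tukey `k` | 1.5 | — | the standard fence; scale-free, no distributional assumption |
| DBA `target_length` | median member length | points | avoids resampling bias toward long members |

Local time is UTC plus a fixed minute offset; there are no DST shifts, so
every slot spans exactly `tau` clock hours. Weeks start Monday; the weekend
is Saturday and Sunday. Mode ties in GPS downsampling go to the
first-observed pair; rounding is half-to-even. All of these choices are
fixed so that a rerun with the same config reproduces segment identities
bit for bit.

## Numerical and design choices where the design was open

- **Column dissimilarity.** "Most dissimilar column" is operationalized as
  the mean of a row's off-diagonal, non-missing entries (median available).
  Missing entries (pairs failing a metric precondition) are excluded from
  aggregation, never zero-filled; for clustering only, they are imputed at
  the maximum observed distance so incomparable segments do not cluster
  together.
- **Anomaly criterion.** No specific fence is canonical for TAS scores; the
  Tukey fence is the default because it is scale-free and robust, and the
  quantile rule is provided because its flags are invariant under any
  strictly increasing transform of the scores.
- **Third metric.** The lock-step mean Euclidean distance is this package's
  choice of an alignment-free comparison and is labelled `lockstep` in all
  outputs.
- **DBA monotonicity.** The barycenter update replaces each baseline value
  with the mean of the member values DTW-warped onto it. Because the mean
  minimizes squared — not absolute — cost, a mean update is not formally
  guaranteed to lower the summed-DTW objective; the iteration therefore
  rejects any worsening update and stops, making the recorded objective
  history non-increasing by construction. Initialization is the group
  medoid (lowest index on ties), so runs are fully deterministic.
- **Correlation pairing.** Pooled participant-days is the default;
  per-participant averaging of coefficients is first-class (its p-value
  comes from a t-test on Fisher-z transformed per-participant
  coefficients). No multiple-testing correction is applied by default.
- **tau = 24.** Whole-day segments are admitted as the "daily" special case
  alongside 0 < tau < 24, since daily calendar scores require one value per
  date.

## What the synthetic generator emulates — and what it does not

`tas.simulate` produces schema-exact streams for a configurable daily
routine: anchor locations (default home + workplace, 0.07 degrees apart)
with hour schedules and linear 20-min commutes, Gaussian GPS noise
(SD 0.0003 degrees, below one rounding cell, so mode-downsampling is
exercised meaningfully), hour-of-day activity and screen-use profiles, and
independent per-hour dropout. The dropout default (2%) is a calibration
constraint of the generator: dropped hours shorten a day's trajectory and
skew its DTW distances right, and the default is set so that on
anomaly-free streams the Tukey fence flags at most 10% of daily scores
(at 5% dropout that bound is violated). GPS is emitted every 30 s
(honouring the 1 Hz collection cap while matching the resolution the
analysis works at; a 1 Hz emission mode exists and is tested on short
windows), accelerometer at 5 Hz, screen as alternating on/off sessions.
One seed feeds a splittable per-sensor RNG, so streams are byte-reproducible
and independently regenerable. Planted anomalies displace GPS by a chosen
magnitude in chosen hours, shift schedules in time, or damp accelerometer
fluctuation; surveys are daily 0-3 Likert scores optionally coupled
additively to the planted days.

The generator does **not** model road networks, transport modes, location
semantics, weekly or seasonal routine drift, correlated multi-sensor
dropout, or realistic symptom dynamics. Passing tests therefore show that
the pipeline recovers planted deviations from a stable synthetic routine —
not that it detects clinical change in real cohorts, whose effect sizes
(correlations around 0.1-0.2 in comparable field studies) are far below the
planted effects used here.

## Validation experiments and problem sizes

`tas.experiments` (driven by `scripts/acceptance.py` and the acceptance
tests) uses 28-day single-participant GPS streams downsampled at 120-s
intervals — a coarser, user-specified resolution that keeps hundreds of
seeded end-to-end runs cheap while preserving the routine structure:

- **Planted-day recovery** (100 seeds): one displaced-location day
  (+0.05 degrees latitude, ~5.5 km, hours 8-19) must top the daily DTW-TAS
  ranking.
- **Null calibration** (100 seeds): with no anomaly, the fraction of days
  flagged by the default Tukey fence; scores are right-skewed (days with
  more dropped hours sit farther from the rest), which is why this rate is
  a binding constraint on the generator's dropout default rather than a
  trivially satisfied one.
- **Hourly localization** (fixed seed): a 1.0-degree (~110 km) excursion in
  hours 16-19 — an order of magnitude beyond the home-work footprint — must
  occupy the top 4 of the 24-slot profile. Dropout is disabled in this
  fixture so every planted hour is observed.
- **Cluster recovery** (20 seeds): days 15-28 displaced by 0.3 degrees form
  a second routine family; an average-linkage cut at k = 2 must recover the
  two families (ARI).
- **Correlation power / size** (100 seeds each): six displaced days coupled
  to surveys with a one-point Likert shift against noise SD 0.3 must be
  detected (r > 0, p < 0.05); with the coupling off, the rejection rate
  must sit near the nominal 5%.

Kernel-level checks run the DTW and LCSS dynamic programs against
independent oracles: exhaustive warp-path enumeration (m, n <= 5),
exhaustive common-subsequence recursion (m, n <= 8), and a second,
independently written DTW dynamic program (m, n <= 50, agreement to 1e-9).

## Known limitations

- Degree-space Euclidean distance on (lat, lon) is anisotropic away from
  the equator; it is the default for fidelity to common practice in this
  setting, with haversine meters one flag away.
- LCSS and lock-step treat trajectories as sequences; actual timestamps
  within a segment do not enter the distances (alignment is ordinal, not
  temporal).
- The lock-step metric truncates to the common length and so ignores the
  tail of the longer segment.
- Tukey flags within a group assume enough segments (>= 3) for quartiles to
  mean anything; early in a collection window flags are withheld.
- Fixed-offset local time misassigns slots across a real DST transition by
  one hour on the transition day.
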