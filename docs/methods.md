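# Methods

This note documents the models behind `divekit`: what the synthetic trip
generator emulates, how each analysis stage is defined, the numerical choices
that matter, and what the validation suite does and does not demonstrate.

## Synthetic trip generator

The generator (`divekit.simulate`) emulates the data products of
satellite-relay dive loggers on southern elephant seals: per-dive 1-Hz depth
profiles, per-segment accelerometer summaries (summed lateral-axis swimming
effort and prey-catch-attempt seconds — the tag's on-board products; raw
16-Hz acceleration is not simulated), post-dive surface intervals, haul-outs
and a morphometrics table. Two cohort presets encode the default study
conditions:

- **Juveniles** (`juvenile_defaults`): 20 individuals, one recorded dive per
  2 h, trips up to 338 days. By index-based quotas, 17 of 20 depart
  positively buoyant (initial DR ~ N(0.15, 0.04) m/s; the rest
  N(−0.21, 0.02)), 9 of 20 eventually switch to positive buoyancy, and 8 of
  20 non-switchers lose their tags between days 20 and 100 (early
  mortality). Quotas, not Bernoulli draws, so the default cohort hits the
  cohort counts exactly and growing the cohort never reshuffles earlier
  individuals (each individual also has its own `SeedSequence`-spawned
  stream).
- **Adult females** (`adult_defaults`): 9 individuals recorded continuously
  for 70 days (the 2–3 month post-breeding trip), stationary depth
  (474 ± ~80 m) and duration (18.5 ± 5 min) distributions.

**Body-condition template.** Each individual draws a continuous
piecewise-linear drift-rate trajectory. Juveniles: initial DR → trough
(N(−0.22, 0.03) m/s) at day 50 → recovery peak → slow final decline. For
switchers the phase-2 line is anchored to cross zero at a drawn switch day
(N(93, 15) d), with the peak 25 days later; non-switchers draw a peak below
−0.03 m/s (they never reach positive buoyancy). Adults improve linearly from
about −0.25 to −0.08 m/s and never cross zero. The trajectory is the ground
truth (`TrueState`) carried by every record, so recovery error is exactly
computable.

**Dive construction.** Dives are trapezoidal: constant-rate descent/ascent
(1.0–1.5 m/s, drawn per dive), and a bottom phase with foraging excursions
*above* the maximum depth (half-normal wiggles, SD 1.5 m, corners pinned),
so the raw maximum equals the drawn target depth and the broken-stick corner
points are well defined. Juvenile target depth is linear through 115 m at
day 50 and 227 m at month 8 (flat after), with CV 0.18; durations ramp from
8 min at departure to 14 min at day 100 (SD 5 min) — together these place
the trip-wide mean near 12.9 min while keeping departure-phase dives
shorter, as the ontogeny of a developing diver requires. With probability
`drift_dive_prob` (default 0.10; the tagged studies do not report this rate,
so it is exposed as a parameter) the bottom phase is replaced by a passive
drift at the true DR plus N(0, 0.01) m/s noise, starting at
max(80 m, 60% of target depth) and guaranteed ≥ 40% of the dive by flooring
the total duration.

**Effort, PrCA, surfaces.** Active segments get effort rates of
5.5 + 3·|DR| m/s³ plus noise (the active mode of the bimodal effort
distribution — always above the 4 m/s³ filter threshold); passive segments
draw 0.3–2.5 m/s³ with zero PrCA. Bottom PrCA fractions average 0.10 for
adults and decay from 0.22 to 0.10 over the first 100 juvenile days
(juveniles forage more often but less efficiently early on). Surface
duration = base + 2·10⁻⁴ min per unit transit effort − 0.3 min per unit
bottom PrCA rate, floored at 30 s, replaced by an extended interval
(3.5 min + Exp(1.5)) with probability 0.013. The bases (0.86 min juvenile,
1.44 min adult) and effort coefficients (2·10⁻⁴ vs 1.2·10⁻⁴, juveniles
steeper) were set once by expectation arithmetic against the cohort means
(1.15 and 2.0 min) given each cohort's mean transit time; the adult base is
higher, matching the slower surface recovery of a larger diver.

**Haul-outs.** Individuals ending their trip positively buoyant haul out
longer (N(8.7, 4.4) d) than negatively buoyant returnees (N(2.9, 2.59) d);
failed tags produce no haul-out.

**What the generator does not emulate:** geographic movement, bathymetry and
benthic dive types, Argos location error, within-day behavioral rhythms,
autocorrelated noise, transmission gaps other than whole-tag failure, and
any feedback of foraging success on the condition trajectory (the template
is drawn up front). Passing calibration therefore shows the *pipeline*
recovers what the model generates under realistic magnitudes and sampling —
not that real data contain no further structure.

## Dive abstraction

Broken-stick selection: starting from the dive's endpoints, repeatedly
retain the sample with maximum vertical distance from the current
piecewise-linear reconstruction, until 4 points (3 segments) remain. The
first/last segments are labeled descent/ascent and the interior bottom; with
more retained points (`n_points > 4`, a configuration for richer 6-point
summaries) roles are assigned by contiguity: leading segments sinking faster
than 0.1 m/s are descent, trailing segments rising faster than 0.1 m/s are
ascent, ties toward bottom. Accelerometer summaries are apportioned onto
abstracted segments by duration-weighted time overlap, conserving totals to
machine precision. Maximum depth is taken from the raw profile, never the
reconstruction. Profiles shorter than 10 s or never exceeding 15 m (the
standard TDR dive threshold) are rejected as non-dives.

On noise-free piecewise-linear dives the greedy selection coincides with the
exhaustive minimax-optimal point pair (verified against a brute-force oracle
on 500 random profiles); on arbitrarily noisy series greedy selection is not
guaranteed to be the global optimum, which is a property of the transmitted
summaries themselves, not a defect of this implementation.

## Drift filter and condition series

The five rules are applied in the order listed in the README. Numerical
choices: "null vertical speed" (resting on the sea floor) means
|rate| < 10⁻⁶ m/s — the sources give no tolerance; thresholds are treated as
exclusive bounds (exactly 4 m/s³ or exactly 40% survives); if several
segments survive (possible only for >3-segment abstractions) the
duration-weighted mean rate is returned. The relative order of the speed and
duration filters is configurable (`speed_before_fraction`) and verified to
give identical results against an independent oracle either way. The 65-m
drift-start observation is treated as rationale, not a rule; an optional
`min_drift_depth` gate is off by default.

Daily aggregation: per-day median of per-dive estimates, smoothed by a
7-day centered rolling median requiring ≥ 3 daily values — the median
because drift estimates are sparse (~1 per 10 recorded dives) and a single
contaminated segment should not drag a day; 7 days as the shortest window
that bridges the ~28% of days with no drift dive at the juvenile recording
cadence.

## Phases, slopes, BMI

Phase boundaries are defined on the *smoothed* series: the departure phase
ends at its global minimum; a return phase exists only if the post-trough
maximum is followed by a decline ≥ 0.02 m/s (guards against phantom return
phases driven by smoothing noise); the buoyancy switch is the first day
after the trough with smoothed DR > 0 — an initially positive departure is
not a switch. Both detected (default) and fixed (50/100 d) boundary modes
are available; individuals with < 30 days of data fall back to fixed
boundaries. Departure slopes are plain per-individual OLS on daily values —
a deliberate simplification of mixed-effects machinery: with per-individual
reporting, independent fits answer the same question without a random-effects
layer. BMI is the residual of cohort OLS of mass on length (residuals sum
to zero and are orthogonal to length; a zero-variance cohort falls back to
mass centering, with a warning).

## ADL analyses

tADL thresholds default to 6/10/18 min across juvenile phases and 28 min
for adults, applied per individual and pooled as mean ± SD of per-individual
proportions. The behavioral-ADL fit bins durations (1-min bins, ≥ 5 dives
per bin), takes per-bin median surface durations (extended intervals
> 3.5 min excluded first), and fits every two-segment continuous hinge with
the knot at an interior bin edge; a breakpoint is declared only when the
best hinge cuts SSE by ≥ 10% versus a single line *and* steepens above the
knot. The 10% rule operationalizes "no detectable behavioral ADL" without
inventing a significance test; under the default generator (surface linear
in effort, hence roughly linear in duration) both cohorts correctly report
none. Surface-duration relations (vs duration, transit effort, bottom PrCA
rate) are binned-median OLS slopes with seeded bootstrap percentile CIs
(1,000 resamples) — robust to the heavy right tail of surface intervals.

Note that with the simple linear duration ontogeny the central- and
return-phase tADL exceedance proportions are higher than a real cohort
shows; only the departure-phase proportion is a calibrated quantity.

## Problem sizes and determinism

The default end-to-end run processes ~34,000 juvenile and ~43,000 adult
dives (~7·10⁷ depth samples) in about a minute on one CPU; profiles are
streamed per individual and never held cohort-wide. Large recovery
experiments (e.g. switch-day detection over 100 juveniles) use the
generator's estimate-level observation mode, which samples drift estimates
from the same truth templates at the recorded cadence without building 1-Hz
profiles. All randomness descends from a single master seed
(`PipelineConfig.seed` → per-cohort → per-individual streams); identical
configuration yields byte-identical reports, and internal units are strictly
seconds/meters with minutes only at the reporting boundary.

## Known limitations

- The generator's condition template is piecewise-linear; real DR
  trajectories bend smoothly, so phase-boundary detection on real data will
  be less sharp than the recovery tests suggest.
- Benthic dives, haul-out bouts within a trip, and plateau-vs-oceanic
  habitat structure are not modeled.
- The behavioral-ADL criterion (10% SSE reduction) is a pragmatic detection
  rule, not an inferential test; treat reported breakpoints as descriptive.
- Body-composition conversion from drift rate to % lipid is out of scope;
  DR is used only as a relative condition index.
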