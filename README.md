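# divekit

Tools for the computational chain behind first-year southern elephant seal
(*Mirounga leonina*) biologging studies: abstraction of raw 1-Hz dive records
into broken-stick segment summaries, detection of passive **drift dives** to
estimate buoyancy (a proxy for body condition), delineation of foraging-trip
phases from the buoyancy trajectory, and aerobic-dive-limit analyses — plus a
calibrated synthetic trip generator with known ground truth for validating
every step.

Intended users are movement ecologists and biologgers working with
satellite-relay dive loggers (time–depth recorders with on-board
accelerometer processing), and anyone who needs a reproducible, testable
re-implementation of the drift-rate / trip-phase / ADL analysis chain.

## The science in brief

**Drift rate.** During a drift dive a seal stops swimming and sinks or rises
under its own buoyancy. The vertical speed of that passive phase — the drift
rate DR (m/s, upward positive) — tracks the animal's lipid:lean ratio:
fatter seals drift less negatively, and above a body-composition threshold,
positively. Passive segments are isolated from abstracted dives by five
filters applied in order: (1) drop the first and last segments; (2) drop
segments with prey-catch-attempt (PrCA) behavior; (3) drop segments with
swimming effort above 4 m/s³; (4) drop segments with vertical speed outside
[−0.3, 0.6] m/s or null; (5) drop segments shorter than 40% of the dive.

**Trip phases.** A juvenile's daily DR series typically shows three phases:
a departure decline (to a trough near day 50), a central recovery (for some
individuals crossing DR = 0 — the *buoyancy switch*, near day 93), and a
final decline on the return leg. Phase boundaries are read off a 7-day
centered rolling median of the daily series; departure-phase rates of change
come from per-individual OLS fits, and BMI is the residual of a cohort OLS
regression of mass on length.

**Aerobic dive limits.** tADL exceedance is the proportion of dives longer
than a fixed phase-specific threshold (6 / 10 / 18 min across juvenile
phases, 28 min for adult females). The behavioral ADL is the dive duration
at which post-dive surface time inflects upward, fit as a two-segment
continuous piecewise-linear model on binned median surface durations.

**Broken-stick abstraction.** A 1-Hz profile is reduced to 4 points / 3
segments (descent, bottom, ascent) by iteratively retaining the sample
farthest from the current piecewise-linear reconstruction — the same
summary the tags transmit for juveniles, applied identically to the
archived adult records.

## Worked example

```python
import numpy as np
import divekit as dk

params = dk.juvenile_defaults(n_individuals=1, trip_days_max=60, seed=42)
record = dk.simulate_cohort(params)[0]
print(f"{len(record.dives)} dives over {record.truth.trip_end_day:.0f} days")

dives_df, segments_df, summaries = dk.abstract_cohort([record])
est = dk.drift_table(summaries)
print(f"{len(est)} drift-dive estimates pass the five-step filter")

series = dk.daily_drift_series(est, record.individual_id)
phases = dk.segment_phases(series)
print(f"departure phase ends on day {phases.phase1_end:.0f} "
      f"(true trough day {record.truth.phase1_end:.0f})")
sm = series.smoothed.dropna()
truth = record.truth.trajectory(np.asarray(sm.index, float))
rmse = np.sqrt(np.mean((sm.to_numpy() - truth) ** 2))
print(f"drift-rate RMSE vs generating truth: {rmse:.4f} m/s")
```

Output:

```
720 dives over 60 days
81 drift-dive estimates pass the five-step filter
departure phase ends on day 48 (true trough day 50)
drift-rate RMSE vs generating truth: 0.0042 m/s
```

One recorded dive every 2 h for 60 days gives 720 dives; about 10% contain a
passive phase that survives the filter. The detected departure-phase
boundary lands within two days of the generating trough, and the smoothed
daily drift rate tracks the generating body-condition trajectory to a few
mm/s.

## Command line

```bash
divekit simulate  --config cfg.yaml --out raw/            # raw 1-Hz cohort CSVs
divekit abstract  --in raw/ --out dives_abstracted.csv    # broken-stick summaries
divekit drift     --in dives_abstracted.csv --out drift.csv
divekit condition --drift drift.csv --morph raw/morphometrics.csv --out cond/
divekit adl       --in dives_abstracted.csv --phases cond/phases.csv --out adl/
divekit all       --seed 1 --out out/                     # full in-memory pipeline
```

`divekit all` writes per-stage CSVs plus `report.json` / `report.txt` with
every cohort statistic (mean, SD, n). Exit codes: 0 ok, 2 schema error,
3 config error.

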