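"""Drift-segment filter and per-individual daily drift-rate series.

A drift dive contains a prolonged passive phase in which the seal sinks or
rises under its own buoyancy; the vertical speed of that phase (drift rate,
m/s, upward positive) tracks the lipid:lean ratio and is the study's proxy
for body condition.  Candidate passive segments are isolated from abstracted
dive summaries by five filters applied in order:

1. drop the first (descent) and last (ascent) segments;
2. drop segments with any detected prey-catch-attempt behavior;
3. drop segments with swimming effort above 4 m/s^3 (the active mode of the
   bimodal effort distribution);
4. drop segments with vertical speed below -0.3 m/s, above 0.6 m/s, or null
   (resting on the sea floor);
5. drop segments lasting less than 40% of the total dive duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .abstraction import DiveSummary
from .params import FilterThresholds

__all__ = [
    "DriftEstimate",
    "ConditionSeries",
    "FilterCounts",
    "filter_drift_segments",
    "drift_table",
    "daily_drift_series",
]


@dataclass
class DriftEstimate:
    dive_id: str
    individual_id: str
    day: float
    drift_rate: float                   # m/s, upward positive, in [-0.3, 0.6] \ {0}
    segment_duration_fraction: float    # surviving-segment share of dive time, >= 0.40


@dataclass
class FilterCounts:
    """Per-step drop counts, for provenance logging."""

    dives: int = 0
    step1_edges: int = 0
    step2_prca: int = 0
    step3_effort: int = 0
    step4_speed: int = 0
    step5_fraction: int = 0
    kept: int = 0

    def as_dict(self) -> dict:
        return dict(dives=self.dives, step1_edges=self.step1_edges,
                    step2_prca=self.step2_prca, step3_effort=self.step3_effort,
                    step4_speed=self.step4_speed, step5_fraction=self.step5_fraction,
                    kept=self.kept)


def _speed_ok(rate: float, thr: FilterThresholds) -> bool:
    if rate < thr.speed_min or rate > thr.speed_max:
        return False
    if abs(rate) < thr.null_tol:    # null speed: resting on the ocean floor
        return False
    return True


def filter_drift_segments(dive: DiveSummary, thresholds: FilterThresholds | None = None,
                          counts: Optional[FilterCounts] = None) -> Optional[DriftEstimate]:
    """Apply the five-step drift filter to one abstracted dive.

    Returns the dive's drift-rate estimate, or ``None`` when no passive
    segment survives (a normal outcome, not an error).  When several segments
    survive (possible only with >3-segment abstractions) the duration-weighted
    mean rate is returned.
    """
    thr = thresholds or FilterThresholds()
    if counts is not None:
        counts.dives += 1
    segs = dive.segments
    if len(segs) < 3:
        return None

    # step 1: remove descent (first) and ascent (last)
    candidates = segs[1:-1]
    if counts is not None:
        counts.step1_edges += 2

    # step 2: any PrCA behavior
    kept = [s for s in candidates if s.prca_fraction <= 0.0]
    if counts is not None:
        counts.step2_prca += len(candidates) - len(kept)
    candidates = kept

    # step 3: swimming effort above the active/passive split
    kept = [s for s in candidates if s.effort_rate <= thr.effort_max]
    if counts is not None:
        counts.step3_effort += len(candidates) - len(kept)
    candidates = kept

    def speed_filter(cands):
        out = [s for s in cands if _speed_ok(s.vertical_rate, thr)]
        if counts is not None:
            counts.step4_speed += len(cands) - len(out)
        return out

    def fraction_filter(cands):
        out = [s for s in cands if s.duration >= thr.min_fraction * dive.duration]
        if counts is not None:
            counts.step5_fraction += len(cands) - len(out)
        return out

    # steps 4 and 5 (order configurable; the published order is speed first)
    if thr.speed_before_fraction:
        candidates = fraction_filter(speed_filter(candidates))
    else:
        candidates = speed_filter(fraction_filter(candidates))

    if thr.min_drift_depth is not None:
        candidates = [s for s in candidates
                      if max(s.depth_start, s.depth_end) >= thr.min_drift_depth]

    if not candidates:
        return None
    if counts is not None:
        counts.kept += 1
    total_dur = sum(s.duration for s in candidates)
    rate = sum(s.vertical_rate * s.duration for s in candidates) / total_dur
    return DriftEstimate(dive_id=dive.dive_id, individual_id=dive.individual_id,
                         day=dive.day, drift_rate=float(rate),
                         segment_duration_fraction=float(total_dur / dive.duration))


def drift_table(dives: Iterable[DiveSummary], thresholds: FilterThresholds | None = None,
                counts: Optional[FilterCounts] = None) -> pd.DataFrame:
    """Run the filter over many dives; one row per surviving estimate."""
    rows = []
    for d in dives:
        est = filter_drift_segments(d, thresholds, counts)
        if est is not None:
            rows.append({"individual_id": est.individual_id, "dive_id": est.dive_id,
                         "day": est.day, "drift_rate": est.drift_rate,
                         "fraction": est.segment_duration_fraction})
    return pd.DataFrame(rows, columns=["individual_id", "dive_id", "day",
                                       "drift_rate", "fraction"])


@dataclass
class ConditionSeries:
    """Per-individual daily drift-rate series (proxy for body condition)."""

    individual_id: str
    daily: pd.Series        # per-day median drift rate; NaN on days without estimates
    smoothed: pd.Series     # centered rolling median of `daily`

    @property
    def days_with_data(self) -> int:
        return int(self.daily.notna().sum())


def daily_drift_series(estimates: pd.DataFrame, individual_id: str = "",
                       window: int = 7, min_obs: int = 3) -> ConditionSeries:
    """Aggregate per-dive drift estimates into a daily condition series.

    ``estimates`` needs columns ``day`` and ``drift_rate`` (one individual).
    Days are whole days since departure; the per-day statistic is the median,
    smoothed by a centered rolling median over ``window`` days requiring at
    least ``min_obs`` daily values in the window.  Empty input yields an
    empty series.
    """
    if len(estimates) == 0:
        empty = pd.Series(dtype=float, name="drift_rate")
        return ConditionSeries(individual_id, empty, empty.copy())
    day = np.floor(estimates["day"].to_numpy()).astype(int)
    daily = (estimates.assign(_day=day).groupby("_day")["drift_rate"].median())
    full_index = pd.RangeIndex(int(daily.index.min()), int(daily.index.max()) + 1, name="day")
    daily = daily.reindex(full_index)
    smoothed = daily.rolling(window=window, center=True, min_periods=min_obs).median()
    return ConditionSeries(individual_id, daily.rename("drift_rate"),
                           smoothed.rename("drift_rate_smoothed"))
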