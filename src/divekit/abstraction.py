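"""Broken-stick abstraction of 1-Hz dive profiles into segment summaries.

Mirrors the on-board abstraction of satellite-relay dive loggers: a dive is
reduced to a small set of inflection points by iteratively retaining the
sample farthest (vertically) from the current piecewise-linear
reconstruction.  Four points / three segments is the default, matching the
descent–bottom–ascent summaries transmitted for juveniles; more points can be
retained, in which case segments are collapsed onto the three roles by a
leading-descent / trailing-ascent rule.

Tag accelerometer summaries (swimming-effort sums and PrCA seconds, produced
per true dive phase) are mapped onto the abstracted segments by
duration-weighted time overlap, conserving totals exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import AccelSegment, DepthSeries, TripRecord

__all__ = [
    "NotADiveError",
    "DiveSegment",
    "DiveSummary",
    "broken_stick_points",
    "abstract_dive",
    "dive_metrics",
    "abstract_cohort",
]

MIN_DIVE_SAMPLES = 10
MIN_DIVE_DEPTH = 15.0   # m; shallower excursions are surface behavior, not dives
SURFACE_DEPTH = 5.0


class NotADiveError(ValueError):
    """Profile rejected as a non-dive (too short or never below 15 m)."""


@dataclass
class DiveSegment:
    segment_idx: int
    t_start: float              # s from dive start
    t_end: float
    depth_start: float          # m
    depth_end: float
    vertical_rate: float        # m/s, upward positive: (depth_start - depth_end)/dt
    effort_sum: float           # m/s^2 summed over the segment
    effort_rate: float          # m/s^3 = effort_sum / duration
    prca_fraction: float        # fraction of segment time spent in prey catch attempts
    role: str                   # {"descent", "bottom", "ascent"}

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class DiveSummary:
    dive_id: str
    individual_id: str
    day: float                  # days since departure
    max_depth: float            # m, maximum of the raw profile
    duration: float             # s
    surface_duration: float     # s
    segments: list[DiveSegment]
    age_class: str = "juvenile"
    habitat_flag: Optional[str] = None


def broken_stick_points(depth: np.ndarray, n_points: int = 4) -> np.ndarray:
    """Indices of the retained inflection points (endpoints always included).

    Iteratively adds the sample with maximum vertical distance from the
    current piecewise-linear reconstruction until ``n_points`` are kept.
    """
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    if n < 2:
        raise ValueError("profile needs at least 2 samples")
    t = np.arange(n, dtype=float)
    knots = [0, n - 1]
    while len(knots) < min(n_points, n):
        ks = sorted(knots)
        recon = np.interp(t, t[ks], depth[ks])
        dev = np.abs(depth - recon)
        dev[ks] = -1.0
        knots.append(int(np.argmax(dev)))
    return np.array(sorted(knots))


def _assign_roles(rates: Sequence[float]) -> list[str]:
    """Descent = contiguous leading segments sinking faster than 0.1 m/s,
    ascent = contiguous trailing segments rising faster than 0.1 m/s,
    bottom = remainder (ties broken toward bottom)."""
    k = len(rates)
    if k == 3:
        return ["descent", "bottom", "ascent"]
    roles = ["bottom"] * k
    i = 0
    while i < k - 1 and rates[i] < -0.1:
        roles[i] = "descent"
        i += 1
    j = k - 1
    while j > i and rates[j] > 0.1:
        roles[j] = "ascent"
        j -= 1
    return roles


def _apportion(accel: Sequence[AccelSegment], t_edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Duration-weighted mapping of accel summaries onto abstracted segments."""
    k = len(t_edges) - 1
    effort = np.zeros(k)
    prca = np.zeros(k)
    for seg in accel:
        dur = seg.t_end - seg.t_start
        if dur <= 0:
            continue
        for j in range(k):
            ov = min(seg.t_end, t_edges[j + 1]) - max(seg.t_start, t_edges[j])
            if ov > 0:
                effort[j] += seg.effort_sum * ov / dur
                prca[j] += seg.prca_s * ov / dur
    return effort, prca


def abstract_dive(profile: DepthSeries, accel: Sequence[AccelSegment],
                  surface_s: float = 0.0, n_points: int = 4,
                  dive_id: str = "d0", individual_id: str = "ind0",
                  age_class: str = "juvenile") -> DiveSummary:
    """Reduce one 1-Hz profile to a broken-stick segment summary.

    Raises :class:`NotADiveError` for profiles shorter than
    ``MIN_DIVE_SAMPLES`` or never exceeding ``MIN_DIVE_DEPTH``.
    """
    depth = np.asarray(profile.depth, dtype=float)
    if len(depth) < MIN_DIVE_SAMPLES:
        raise NotADiveError(f"{dive_id}: only {len(depth)} samples (< {MIN_DIVE_SAMPLES})")
    if float(np.max(depth)) <= MIN_DIVE_DEPTH:
        raise NotADiveError(
            f"{dive_id}: max depth {np.max(depth):.1f} m never exceeds {MIN_DIVE_DEPTH} m")
    if n_points < 4:
        raise ValueError("need at least 4 retained points for 3 segments")

    knots = broken_stick_points(depth, n_points)
    t_edges = knots.astype(float)
    d_knots = depth[knots]
    rates = [(d_knots[i] - d_knots[i + 1]) / (t_edges[i + 1] - t_edges[i])
             for i in range(len(knots) - 1)]
    roles = _assign_roles(rates)
    effort, prca = _apportion(accel, t_edges)

    segments = []
    for i in range(len(knots) - 1):
        dur = t_edges[i + 1] - t_edges[i]
        segments.append(DiveSegment(
            segment_idx=i,
            t_start=float(t_edges[i]), t_end=float(t_edges[i + 1]),
            depth_start=float(d_knots[i]), depth_end=float(d_knots[i + 1]),
            vertical_rate=float(rates[i]),
            effort_sum=float(effort[i]),
            effort_rate=float(effort[i] / dur),
            prca_fraction=float(np.clip(prca[i] / dur, 0.0, 1.0)),
            role=roles[i]))

    day = profile.t0_s / 86400.0
    return DiveSummary(dive_id=dive_id, individual_id=individual_id, day=day,
                       max_depth=float(np.max(depth)), duration=float(len(depth) - 1),
                       surface_duration=float(surface_s), segments=segments,
                       age_class=age_class)


def dive_metrics(summary: DiveSummary) -> dict:
    """Per-dive analysis metrics in reporting units (minutes at this boundary)."""
    total_effort = sum(s.effort_sum for s in summary.segments
                       if s.role in ("descent", "ascent"))
    bottom = [s for s in summary.segments if s.role == "bottom"]
    if bottom:
        bdur = sum(s.duration for s in bottom)
        bottom_prca_rate = sum(s.prca_fraction * s.duration for s in bottom) / bdur
    else:
        bottom_prca_rate = np.nan
    return {
        "dive_id": summary.dive_id,
        "individual_id": summary.individual_id,
        "day": summary.day,
        "max_depth_m": summary.max_depth,
        "duration_min": summary.duration / 60.0,
        "surface_min": summary.surface_duration / 60.0,
        "total_effort": total_effort,
        "bottom_prca_rate": bottom_prca_rate,
    }


def abstract_cohort(records: Iterable[TripRecord], n_points: int = 4,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, list[DiveSummary]]:
    """Abstract every dive of a cohort; returns (dives, segments) tables plus
    the summary objects for downstream per-dive filtering."""
    dive_rows, seg_rows, summaries = [], [], []
    for rec in records:
        for k, d in enumerate(rec.dives):
            dive_id = f"{rec.individual_id}_{k:05d}"
            try:
                s = abstract_dive(d.profile, d.accel, surface_s=d.surface_s,
                                  n_points=n_points, dive_id=dive_id,
                                  individual_id=rec.individual_id,
                                  age_class=rec.age_class)
            except NotADiveError:
                continue
            summaries.append(s)
            dive_rows.append({
                "dive_id": dive_id, "individual_id": rec.individual_id,
                "age_class": rec.age_class, "day": s.day,
                "t0_s": d.profile.t0_s, "duration_s": s.duration,
                "surface_s": s.surface_duration, "max_depth_m": s.max_depth,
            })
            for seg in s.segments:
                seg_rows.append({
                    "dive_id": dive_id, "segment_idx": seg.segment_idx,
                    "role": seg.role, "t_start_s": seg.t_start, "t_end_s": seg.t_end,
                    "depth_start_m": seg.depth_start, "depth_end_m": seg.depth_end,
                    "vertical_rate": seg.vertical_rate, "effort_sum": seg.effort_sum,
                    "effort_rate": seg.effort_rate, "prca_fraction": seg.prca_fraction,
                })
    dives_df = pd.DataFrame(dive_rows)
    segments_df = pd.DataFrame(seg_rows)
    return dives_df, segments_df, summaries
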