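"""Synthetic trip generator with known ground truth.

Emulates the raw products of satellite-relayed dive/accelerometer tags on
southern elephant seals: 1-Hz depth profiles, per-segment lateral-axis
swimming-effort sums and prey-catch-attempt (PrCA) seconds, post-dive surface
intervals and haul-outs.  The body-condition trajectory of each individual is
a piecewise-linear drift-rate template (decline after departure, recovery in a
central phase, final decline on the return leg for juveniles; a monotone
improvement that never reaches positive buoyancy for adult females), and every
simulated record carries that generating truth so downstream recovery error is
computable exactly.

Time is seconds, depth meters (positive down), vertical rates m/s (positive
up), throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .params import GeneratorParams

__all__ = [
    "DepthSeries",
    "AccelSegment",
    "SimulatedDive",
    "TrueState",
    "TripRecord",
    "ConditionTrajectory",
    "condition_model",
    "draw_condition_trajectory",
    "simulate_dive",
    "simulate_individual",
    "simulate_cohort",
    "iter_cohort",
    "simulate_drift_observations",
    "cohort_checksum",
]

DRIFT_RATE_BAND = (-0.3, 0.6)  # physically plausible passive vertical speeds, m/s


@dataclass
class DepthSeries:
    """One dive's 1-Hz depth record. ``depth[k]`` is the sample at t0_s + k."""

    t0_s: float                 # dive start, seconds since departure
    depth: np.ndarray           # m, positive down; starts and ends at the surface

    @property
    def duration_s(self) -> int:
        return len(self.depth) - 1

    @property
    def max_depth(self) -> float:
        return float(np.max(self.depth))


@dataclass
class AccelSegment:
    """Tag-produced accelerometer summary for one true dive segment."""

    t_start: float              # s from dive start
    t_end: float
    effort_sum: float           # summed lateral-axis acceleration, m/s^2
    prca_s: float               # seconds of prey-catch-attempt behavior


@dataclass
class SimulatedDive:
    profile: DepthSeries
    accel: list[AccelSegment]
    surface_s: float
    day: float                  # days since departure at dive start
    is_drift: bool
    dr_true: float              # generating drift rate at dive time, m/s
    drift_rate_realized: Optional[float] = None  # dr_true + noise, drift dives only


@dataclass
class ConditionTrajectory:
    """Piecewise-linear drift-rate template for one individual."""

    knot_days: np.ndarray
    knot_dr: np.ndarray

    def __post_init__(self) -> None:
        self.knot_days = np.asarray(self.knot_days, dtype=float)
        self.knot_dr = np.asarray(self.knot_dr, dtype=float)
        if len(self.knot_days) != len(self.knot_dr):
            raise ValueError("knot_days and knot_dr must have equal length")
        if np.any(np.diff(self.knot_days) <= 0):
            raise ValueError("knot_days must be strictly increasing")

    def __call__(self, day):
        return np.interp(day, self.knot_days, self.knot_dr)


@dataclass
class TrueState:
    """Generating ground truth for one individual."""

    trajectory: ConditionTrajectory
    switch_day: Optional[float]         # true zero-crossing day, None if never positive
    phase1_end: Optional[float]         # trough day of the template
    phase2_end: Optional[float]         # peak day of the template
    trip_end_day: float                 # last day with dives (haul-out or tag death)
    tag_failure_day: Optional[float]    # None if the tag survived the trip

    def dr_daily(self, n_days: Optional[int] = None) -> pd.Series:
        n = int(np.ceil(self.trip_end_day)) if n_days is None else n_days
        days = np.arange(n)
        return pd.Series(self.trajectory(days), index=days, name="dr_true")


@dataclass
class TripRecord:
    individual_id: str
    age_class: str
    mass_kg: float
    length_cm: float
    departure_day: float
    dives: list[SimulatedDive]
    haul_outs: list[tuple[float, float]]    # (start_day, end_day)
    truth: TrueState


def condition_model(day, params: GeneratorParams,
                    individual_offsets: ConditionTrajectory):
    """True drift rate (m/s) on ``day`` for an individual's drawn trajectory.

    ``individual_offsets`` carries the individual's knots (initial drift rate,
    trough, recovery peak, final value and their days); the template itself is
    continuous piecewise-linear.
    """
    day = np.asarray(day, dtype=float)
    if np.any(day < 0):
        raise ValueError("day must be >= 0")
    return individual_offsets(day)


def draw_condition_trajectory(params: GeneratorParams, rng: np.random.Generator,
                              positive_init: bool = True,
                              switcher: bool = False) -> tuple[ConditionTrajectory, dict]:
    """Draw one individual's drift-rate template.

    Juveniles get the three-phase template (decline to a trough near
    ``dr_phase1_end``, recovery to a peak — above zero only for switchers —
    then a slow final decline).  Adults get a two-knot monotone improvement
    that stays negative.  Returns the trajectory plus the drawn anchor values.
    """
    horizon = params.trip_days_max
    if params.age_class == "adult":
        dr0 = float(np.clip(rng.normal(params.dr_init_mean, params.dr_init_sd),
                            -0.29, -0.05))
        dr1 = float(np.clip(rng.normal(params.dr_adult_final_mean, params.dr_adult_final_sd),
                            dr0 + 0.01, -0.02))
        traj = ConditionTrajectory(np.array([0.0, horizon]), np.array([dr0, dr1]))
        return traj, {"dr_init": dr0, "switch_day": None,
                      "phase1_end": None, "phase2_end": None}

    if positive_init:
        dr0 = float(np.clip(rng.normal(params.dr_init_mean, params.dr_init_sd), 0.03, 0.28))
    else:
        dr0 = float(np.clip(rng.normal(params.dr_init_neg_mean, params.dr_init_neg_sd),
                            -0.27, -0.05))
    p1 = params.dr_phase1_end
    trough = float(np.clip(rng.normal(params.dr_trough_mean, params.dr_trough_sd),
                           -0.28, dr0 - 0.05))

    if switcher:
        switch_day = float(np.clip(rng.normal(params.dr_switch_day_mean,
                                              params.dr_switch_day_sd),
                                   p1 + 10.0, max(p1 + 15.0, horizon - 20.0)))
        slope2 = -trough / (switch_day - p1)
        peak_day = switch_day + params.peak_margin_days
        peak = float(min(trough + slope2 * (peak_day - p1), 0.45))
    else:
        switch_day = None
        peak_day = float(np.clip(rng.normal(100.0, 10.0), p1 + 10.0,
                                 max(p1 + 15.0, horizon - 10.0)))
        peak = float(min(trough + rng.uniform(0.05, 0.19), -0.03))

    s3 = rng.uniform(params.phase3_slope_min, params.phase3_slope_max)
    floor = max(trough + 0.03, -0.28)
    # template horizon always extends past the peak so the knots stay ordered
    # even for short trips (evaluation never goes beyond the trip itself)
    h_t = max(horizon, peak_day + 30.0)
    end_val = float(max(peak - s3 * (h_t - peak_day), floor))
    traj = ConditionTrajectory(np.array([0.0, p1, peak_day, h_t]),
                               np.array([dr0, trough, peak, end_val]))
    return traj, {"dr_init": dr0, "switch_day": switch_day,
                  "phase1_end": p1, "phase2_end": peak_day}


def _mean_depth(day: float, params: GeneratorParams) -> float:
    if params.age_class == "adult":
        return params.adult_depth_mean
    # linear through (50 d, depth@50) and (240 d, depth@month8), flat after
    slope = (params.depth_mean_month8 - params.depth_mean_day50) / 190.0
    d = min(day, 240.0)
    return params.depth_mean_day50 + slope * (d - 50.0)


def _mean_duration_s(day: float, params: GeneratorParams) -> float:
    if params.dur_ramp_days <= 0:
        return params.dive_dur_mean * 60.0
    frac = min(day / params.dur_ramp_days, 1.0)
    mu = params.dive_dur_day0_mean + frac * (params.dive_dur_mean - params.dive_dur_day0_mean)
    return mu * 60.0


def _prca_fraction(day: float, params: GeneratorParams, rng: np.random.Generator) -> float:
    if params.age_class == "adult":
        base = params.prca_adult_scale
    else:
        ontogeny = params.prca_ontogeny_gain * max(0.0, (100.0 - day) / 100.0)
        base = params.prca_juv_scale * (1.0 + ontogeny)
    return float(np.clip(rng.normal(base, params.prca_sd), 0.02, 0.6))


def _active_effort_rate(dr_true: float, params: GeneratorParams,
                        rng: np.random.Generator) -> float:
    mu = params.effort_neutral_min + params.effort_buoyancy_coef * abs(dr_true)
    return float(max(rng.normal(mu, params.effort_noise_sd), 0.0))


def simulate_dive(day: float, dr_true: float, params: GeneratorParams,
                  rng: np.random.Generator, t0_s: float = 0.0,
                  force_drift: Optional[bool] = None) -> SimulatedDive:
    """Simulate one dive: 1-Hz profile, segment accel summaries, surface interval.

    With probability ``drift_dive_prob`` the bottom phase is replaced by a
    passive drift whose vertical rate is ``dr_true`` plus small noise, starting
    below ``drift_min_start_depth`` and occupying at least
    ``drift_frac_target`` of the dive; otherwise an active bottom with
    foraging wiggles, high swimming effort and PrCA.  Raises ``ValueError``
    when ``dr_true`` lies outside the physical drift band (−0.3, 0.6) m/s.
    """
    lo, hi = DRIFT_RATE_BAND
    if not lo < dr_true < hi:
        raise ValueError(
            f"dr_true={dr_true:.3f} m/s outside the physical drift band ({lo}, {hi})")

    target = float(np.clip(rng.normal(_mean_depth(day, params),
                                      params.depth_cv * _mean_depth(day, params)),
                           params.depth_min, params.depth_max))
    dur_draw = float(np.clip(rng.normal(_mean_duration_s(day, params),
                                        params.dive_dur_sd * 60.0),
                             params.dive_dur_min * 60.0, params.dive_dur_max * 60.0))
    rd = rng.uniform(params.descent_rate_min, params.descent_rate_max)
    ra = rng.uniform(params.descent_rate_min, params.descent_rate_max)
    is_drift = (rng.random() < params.drift_dive_prob) if force_drift is None else force_drift

    if is_drift:
        dive = _build_drift_dive(day, dr_true, target, dur_draw, rd, ra, params, rng, t0_s)
    else:
        dive = _build_active_dive(day, dr_true, target, dur_draw, rd, ra, params, rng, t0_s)

    # post-dive surface interval from transit effort and foraging intensity
    e_total = dive.accel[0].effort_sum + dive.accel[-1].effort_sum
    bottom = dive.accel[1]
    prca_rate = bottom.prca_s / (bottom.t_end - bottom.t_start)
    surf_min = (params.surf_base
                + params.surf_effort_coef * e_total
                - params.surf_prca_coef * prca_rate
                + rng.normal(0.0, params.surf_noise_sd))
    surf_min = max(surf_min, params.surf_floor)
    if rng.random() < params.extended_surf_prob:
        surf_min = params.extended_surf_min + rng.exponential(params.extended_surf_exp_mean)
    dive.surface_s = surf_min * 60.0
    return dive


def _build_active_dive(day, dr_true, target, dur_draw, rd, ra, params, rng, t0_s):
    travel = target / rd + target / ra
    total = max(dur_draw, travel + 60.0)
    b1 = int(np.clip(round(target / rd), 1, None))
    b2 = int(round(b1 + (total - travel)))
    n = int(round(b2 + target / ra))
    b2 = min(b2, n - 1)

    t = np.arange(n + 1, dtype=float)
    depth = np.interp(t, [0.0, b1, b2, n], [0.0, target, target, 0.0])
    if b2 - b1 > 1:
        interior = slice(b1 + 1, b2)
        wiggle = np.abs(rng.normal(0.0, params.bottom_wiggle_sd, b2 - b1 - 1))
        depth[interior] = np.maximum(depth[interior] - wiggle, 0.0)

    prca_frac = _prca_fraction(day, params, rng)
    accel = [
        AccelSegment(0.0, b1, _active_effort_rate(dr_true, params, rng) * b1, 0.0),
        AccelSegment(b1, b2, _active_effort_rate(dr_true, params, rng) * (b2 - b1),
                     prca_frac * (b2 - b1)),
        AccelSegment(b2, n, _active_effort_rate(dr_true, params, rng) * (n - b2), 0.0),
    ]
    return SimulatedDive(DepthSeries(t0_s, depth), accel, 0.0, day, False, dr_true)


def _build_drift_dive(day, dr_true, target, dur_draw, rd, ra, params, rng, t0_s):
    start = max(params.drift_min_start_depth, 0.6 * target)
    start = min(start, params.depth_max - 10.0)
    dr = dr_true + (rng.normal(0.0, params.drift_noise_sd) if params.drift_noise_sd > 0 else 0.0)
    dr = float(np.clip(dr, -0.295, 0.595))

    travel0 = start / rd + start / ra
    f = params.drift_frac_target
    d_min = travel0 / max(1.0 - f * (1.0 - dr / ra), 0.05)
    total = max(dur_draw, d_min)
    t_drift = (total - travel0) / (1.0 - dr / ra)
    end = start - dr * t_drift
    if end < 20.0 or end > params.depth_max:
        end = float(np.clip(end, 20.0, params.depth_max))
        t_drift = (start - end) / dr if abs(dr) > 1e-9 else t_drift

    b1 = int(np.clip(round(start / rd), 1, None))
    b2 = int(round(b1 + t_drift))
    b2 = max(b2, b1 + 1)
    n = int(round(b2 + end / ra))
    n = max(n, b2 + 1)
    # realized passive rate after snapping boundaries to whole seconds
    end = float(np.clip(start - dr * (b2 - b1), 1.0, params.depth_max))

    t = np.arange(n + 1, dtype=float)
    depth = np.interp(t, [0.0, b1, b2, n], [0.0, start, end, 0.0])
    dr_realized = (start - end) / (b2 - b1)

    drift_rate_eff = rng.uniform(params.drift_effort_lo, params.drift_effort_hi)
    accel = [
        AccelSegment(0.0, b1, _active_effort_rate(dr_true, params, rng) * b1, 0.0),
        AccelSegment(b1, b2, drift_rate_eff * (b2 - b1), 0.0),
        AccelSegment(b2, n, _active_effort_rate(dr_true, params, rng) * (n - b2), 0.0),
    ]
    return SimulatedDive(DepthSeries(t0_s, depth), accel, 0.0, day, True, dr_true,
                         drift_rate_realized=float(dr_realized))


def _quota_flags(n: int, frac: float) -> np.ndarray:
    """Deterministic largest-remainder-free quota: flags[i] set so that any
    prefix of length m contains floor(m*frac)..ceil(m*frac) set flags and the
    total is round-robin stable when n grows."""
    idx = np.arange(n + 1)
    counts = np.floor((idx * frac) + 1e-9).astype(int)
    return (np.diff(counts) > 0)


def _assign_roles(params: GeneratorParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-individual flags (positive_init, switcher, early_fail).

    Index-based quotas so that the default juvenile cohort of 20 yields
    exactly 17 initially positive individuals, 9 buoyancy switchers and 8
    early tag failures, and adding individuals never changes the flags (or
    the random streams) of earlier ones.
    """
    n = params.n_individuals
    if params.age_class == "adult":
        return (np.zeros(n, bool), np.zeros(n, bool), np.zeros(n, bool))
    positive = _quota_flags(n, params.positive_init_frac)
    switcher = _quota_flags(n, params.switch_frac)
    # failures among non-switchers, by non-switcher ordinal (prefix-stable)
    fail = np.zeros(n, bool)
    non_switch = np.flatnonzero(~switcher)
    if len(non_switch):
        frac = min(1.0, params.early_fail_frac / max(1.0 - params.switch_frac, 1e-9))
        fail[non_switch[_quota_flags(len(non_switch), frac)]] = True
    return positive, switcher, fail


def _draw_morphometrics(params: GeneratorParams, rng: np.random.Generator) -> tuple[float, float]:
    r = params.mass_length_corr
    z_len = rng.standard_normal()
    z_res = rng.standard_normal()
    length = params.length_mean + params.length_sd * z_len
    mass = params.mass_mean + params.mass_sd * (r * z_len + np.sqrt(1 - r * r) * z_res)
    return float(max(mass, 5.0)), float(max(length, 40.0))


def simulate_individual(index: int, params: GeneratorParams,
                        seed_seq: np.random.SeedSequence,
                        positive_init: bool, switcher: bool,
                        early_fail: bool) -> TripRecord:
    """Simulate one individual's full trip from its own independent stream."""
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    mass, length = _draw_morphometrics(params, rng)
    traj, anchors = draw_condition_trajectory(params, rng, positive_init, switcher)

    failure_day: Optional[float] = None
    if params.age_class == "adult":
        trip_end = params.trip_days_max
    elif early_fail:
        failure_day = float(rng.uniform(params.early_fail_day_min, params.early_fail_day_max))
        trip_end = min(failure_day, params.trip_days_max)
    elif switcher:
        ret = float(np.clip(rng.normal(params.return_dur_mean, params.return_dur_sd), 15.0, 90.0))
        trip_end = min(anchors["switch_day"] + ret, params.trip_days_max)
    else:
        trip_end = params.trip_days_max

    dives: list[SimulatedDive] = []
    t = 0.0
    horizon_s = trip_end * 86400.0
    interval_s = None if params.dive_interval is None else params.dive_interval * 3600.0
    while t < horizon_s:
        day = t / 86400.0
        dr = float(traj(day))
        dive = simulate_dive(day, dr, params, rng, t0_s=t)
        dives.append(dive)
        if interval_s is None:
            t += dive.profile.duration_s + dive.surface_s
        else:
            t += interval_s

    haul_outs: list[tuple[float, float]] = []
    if failure_day is None and dives:
        final_dr = float(traj(trip_end))
        if final_dr > 0:
            dur = rng.normal(params.haulout_pos_mean, params.haulout_pos_sd)
        else:
            dur = rng.normal(params.haulout_neg_mean, params.haulout_neg_sd)
        dur = float(max(dur, 0.5))
        haul_outs.append((trip_end, trip_end + dur))

    truth = TrueState(trajectory=traj, switch_day=anchors["switch_day"],
                      phase1_end=anchors["phase1_end"], phase2_end=anchors["phase2_end"],
                      trip_end_day=trip_end, tag_failure_day=failure_day)
    prefix = "juv" if params.age_class == "juvenile" else "ad"
    return TripRecord(individual_id=f"{prefix}{index:03d}", age_class=params.age_class,
                      mass_kg=mass, length_cm=length, departure_day=0.0,
                      dives=dives, haul_outs=haul_outs, truth=truth)


def iter_cohort(params: GeneratorParams) -> Iterator[TripRecord]:
    """Lazily yield independent individuals from a shared seed sequence."""
    positive, switcher, fail = _assign_roles(params)
    children = np.random.SeedSequence(params.seed).spawn(params.n_individuals)
    for i in range(params.n_individuals):
        yield simulate_individual(i, params, children[i],
                                  bool(positive[i]), bool(switcher[i]), bool(fail[i]))


def simulate_cohort(params: GeneratorParams) -> list[TripRecord]:
    """Simulate the full cohort (materialized; use :func:`iter_cohort` to stream)."""
    return list(iter_cohort(params))


def simulate_drift_observations(params: GeneratorParams,
                                ) -> list[tuple[str, TrueState, pd.DataFrame]]:
    """Estimate-level observation mode: drift-rate estimates without 1-Hz profiles.

    For every individual, drift estimates are sampled at the cohort's recorded
    drift-dive cadence (Binomial thinning of the dive schedule by
    ``drift_dive_prob``) with the same observation noise the full simulator
    applies to passive segments.  Useful for large recovery experiments where
    generating 1-Hz profiles is unnecessary.
    """
    positive, switcher, fail = _assign_roles(params)
    children = np.random.SeedSequence(params.seed).spawn(params.n_individuals)
    dives_per_day = 24.0 / params.dive_interval if params.dive_interval else 65.0
    out = []
    for i in range(params.n_individuals):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        _draw_morphometrics(params, rng)
        traj, anchors = draw_condition_trajectory(params, rng, bool(positive[i]),
                                                  bool(switcher[i]))
        if params.age_class != "adult" and fail[i]:
            trip_end = float(rng.uniform(params.early_fail_day_min, params.early_fail_day_max))
            failure: Optional[float] = trip_end
        elif params.age_class != "adult" and switcher[i]:
            ret = float(np.clip(rng.normal(params.return_dur_mean, params.return_dur_sd),
                                15.0, 90.0))
            trip_end = min(anchors["switch_day"] + ret, params.trip_days_max)
            failure = None
        else:
            trip_end = params.trip_days_max
            failure = None
        days, rates = [], []
        for d in range(int(np.ceil(trip_end))):
            k = rng.binomial(int(round(dives_per_day)), params.drift_dive_prob)
            for _ in range(k):
                day = d + rng.uniform(0.0, 1.0)
                if day >= trip_end:
                    continue
                days.append(day)
                rates.append(float(traj(day)) + rng.normal(0.0, params.drift_noise_sd))
        truth = TrueState(traj, anchors["switch_day"], anchors["phase1_end"],
                          anchors["phase2_end"], trip_end, failure)
        prefix = "juv" if params.age_class == "juvenile" else "ad"
        df = pd.DataFrame({"day": days, "drift_rate": rates})
        out.append((f"{prefix}{i:03d}", truth, df))
    return out


def cohort_checksum(records: list[TripRecord]) -> int:
    """Order-sensitive checksum over every depth sample, accel summary and
    surface duration — used by the determinism contract."""
    import zlib
    crc = 0
    for rec in records:
        crc = zlib.crc32(rec.individual_id.encode(), crc)
        crc = zlib.crc32(np.array([rec.mass_kg, rec.length_cm]).tobytes(), crc)
        for d in rec.dives:
            crc = zlib.crc32(d.profile.depth.tobytes(), crc)
            crc = zlib.crc32(np.array([d.surface_s, d.day, d.profile.t0_s]).tobytes(), crc)
            for s in d.accel:
                crc = zlib.crc32(np.array([s.t_start, s.t_end, s.effort_sum,
                                           s.prca_s]).tobytes(), crc)
    return crc
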