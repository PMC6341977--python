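"""Trip-phase delineation, departure-phase slopes and body mass index.

The drift-rate trajectory of a first-trip juvenile typically shows three
phases: a departure decline (condition loss while diving skills develop), a
central recovery (successful foraging, for some individuals culminating in a
switch to positive buoyancy), and a final decline on the return leg.  Phase
boundaries are read off the smoothed daily drift-rate series; rates of change
during the departure phase come from per-individual ordinary least squares.
BMI is the residual of a cohort-level OLS regression of body mass on length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .drift import ConditionSeries

__all__ = [
    "InsufficientDataError",
    "TripPhases",
    "SlopeRecord",
    "segment_phases",
    "departure_slope",
    "compute_bmi",
]


class InsufficientDataError(ValueError):
    """Raised when a series is too short for phase or slope estimation."""


@dataclass
class TripPhases:
    individual_id: str
    phase1_end: float                   # day of the smoothed-DR global minimum
    phase2_end: Optional[float]         # day of the post-trough maximum, if a return decline exists
    switch_day: Optional[float]         # first day with smoothed DR > 0

    def phase_of(self, day) -> np.ndarray:
        """Phase label per day: 'departure', 'central' or 'return'."""
        day = np.asarray(day, dtype=float)
        out = np.where(day <= self.phase1_end, "departure", "central")
        if self.phase2_end is not None:
            out = np.where(day > self.phase2_end, "return", out)
        return out


@dataclass
class SlopeRecord:
    individual_id: str
    variable: str                       # {"drift_rate", "dive_duration"}
    intercept: float
    slope: float                        # per day
    intercept_se: float
    slope_se: float
    n_days: int
    window: tuple[float, float]


def segment_phases(series: ConditionSeries, decline_threshold: float = 0.02,
                   min_days: int = 30) -> TripPhases:
    """Delineate trip phases from the smoothed daily drift-rate series.

    phase1_end is the day of the global minimum of the smoothed trajectory;
    phase2_end the day of the subsequent maximum, reported only when the
    series then declines by at least ``decline_threshold`` m/s (guards
    against noise-driven phantom return phases); switch_day the first day
    after the trough with smoothed DR > 0, i.e. the recovery crossing into
    positive buoyancy (an initially positive departure is not a switch).  A
    monotone-decreasing series yields phase1_end = last day and no further
    phases.
    """
    s = series.smoothed.dropna()
    if len(s) < min_days:
        raise InsufficientDataError(
            f"{series.individual_id}: {len(s)} days with data (< {min_days})")

    phase1_end = float(s.idxmin())
    after = s.loc[s.index > phase1_end]
    phase2_end: Optional[float] = None
    if len(after) >= 2:
        peak_day = float(after.idxmax())
        tail = after.loc[after.index >= peak_day]
        if len(tail) >= 2 and (tail.iloc[0] - tail.min()) >= decline_threshold:
            phase2_end = peak_day

    positive = s.loc[(s.index > phase1_end) & (s > 0)]
    switch_day = float(positive.index[0]) if len(positive) else None
    return TripPhases(series.individual_id, phase1_end, phase2_end, switch_day)


def departure_slope(values: pd.Series, phases: TripPhases,
                    variable: str = "drift_rate",
                    min_days: int = 10) -> Optional[SlopeRecord]:
    """OLS line through the phase-1 (departure) daily values.

    ``values`` is a daily series indexed by day.  Returns ``None`` when fewer
    than ``min_days`` days with data fall inside the departure window.
    """
    window = (0.0, phases.phase1_end)
    v = values.dropna()
    v = v.loc[(v.index >= window[0]) & (v.index <= window[1])]
    if len(v) < min_days:
        return None
    x = sm.add_constant(np.asarray(v.index, dtype=float))
    fit = sm.OLS(np.asarray(v, dtype=float), x).fit()
    return SlopeRecord(individual_id=phases.individual_id, variable=variable,
                       intercept=float(fit.params[0]), slope=float(fit.params[1]),
                       intercept_se=float(fit.bse[0]), slope_se=float(fit.bse[1]),
                       n_days=len(v), window=window)


def compute_bmi(morph: pd.DataFrame) -> pd.DataFrame:
    """Body mass index: residuals of the cohort OLS regression of mass on length.

    ``morph`` needs columns ``individual_id``, ``mass_kg``, ``length_cm``.
    Residuals sum to zero and are orthogonal to length by construction.  With
    zero length variance the regression is degenerate and BMI falls back to
    mass centered on the cohort mean (with a warning).
    """
    if len(morph) < 3:
        raise ValueError(f"need >= 3 individuals, got {len(morph)}")
    mass = morph["mass_kg"].to_numpy(dtype=float)
    length = morph["length_cm"].to_numpy(dtype=float)
    if np.any(mass <= 0) or np.any(length <= 0):
        raise ValueError("masses and lengths must be positive")
    out = morph[["individual_id"]].copy()
    out["mass_kg"] = mass
    out["length_cm"] = length
    if np.ptp(length) == 0.0:
        warnings.warn("zero length variance: BMI = mass - cohort mean mass",
                      stacklevel=2)
        out["bmi_kg"] = mass - mass.mean()
        return out
    fit = sm.OLS(mass, sm.add_constant(length)).fit()
    out["bmi_kg"] = fit.resid
    return out
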