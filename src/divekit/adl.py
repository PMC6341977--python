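"""Aerobic-dive-limit analyses.

tADL (theoretical aerobic dive limit) exceedance: the proportion of dives
longer than a fixed phase-specific threshold — 6 min in the departure phase,
10 min central, 18 min return for juveniles; 28 min for adult females.

bADL (behavioral ADL): the dive duration past which post-dive surface time
inflects upward.  Operationalized as a two-segment continuous piecewise-linear
fit to binned median surface durations with the breakpoint searched over
interior bin edges; no breakpoint is reported unless it cuts the single-line
SSE by at least 10% with a steeper upper slope.

Extended surface intervals (> 3.5 min) are flagged and excluded from the
breakpoint and surface-relation fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import TADLThresholds
from .trajectory import TripPhases

__all__ = [
    "BreakpointFit",
    "tadl_exceedance",
    "fit_badl_breakpoint",
    "flag_extended_surfaces",
    "surface_relations",
]


@dataclass
class BreakpointFit:
    breakpoint: Optional[float]     # min, None when no behavioral ADL is detectable
    slope_below: float              # min surface per min dive
    slope_above: float
    loss: float                     # SSE of the selected fit (on binned medians)
    loss_single: float              # SSE of the single-line fit
    n_bins: int
    note: str = ""


def tadl_exceedance(dives: pd.DataFrame, phases: dict[str, TripPhases] | None,
                    thresholds: TADLThresholds | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Proportion of dives exceeding the phase tADL, per individual and pooled.

    ``dives`` needs columns ``individual_id``, ``day``, ``duration_s`` and
    ``age_class``.  ``phases`` maps juvenile individual ids to their
    :class:`TripPhases`; adult dives are compared against the single adult
    threshold.  Returns ``(per_individual, pooled)``; phases with no dives
    are reported as missing, and the pooled table is the mean ± SD of the
    per-individual proportions.
    """
    thr = thresholds or TADLThresholds()
    rows = []
    for ind, g in dives.groupby("individual_id", sort=True):
        dur_min = g["duration_s"].to_numpy(dtype=float) / 60.0
        if (g["age_class"] == "adult").all():
            labels = np.full(len(g), "adult")
        else:
            if phases is None or ind not in phases:
                continue
            labels = phases[ind].phase_of(g["day"].to_numpy())
        for phase in np.unique(labels):
            m = labels == phase
            limit = {"departure": thr.departure, "central": thr.central,
                     "return": thr.return_, "adult": thr.adult}[str(phase)]
            rows.append({"individual_id": ind, "phase": str(phase),
                         "threshold_min": limit, "n_dives": int(m.sum()),
                         "n_exceed": int((dur_min[m] > limit).sum()),
                         "proportion": float((dur_min[m] > limit).mean())})
    per_ind = pd.DataFrame(rows, columns=["individual_id", "phase", "threshold_min",
                                          "n_dives", "n_exceed", "proportion"])
    if len(per_ind):
        pooled = (per_ind.groupby("phase")["proportion"]
                  .agg(mean="mean", sd="std", n="count").reset_index())
    else:
        pooled = pd.DataFrame(columns=["phase", "mean", "sd", "n"])
    return per_ind, pooled


def _piecewise_sse(x: np.ndarray, y: np.ndarray, bp: float) -> tuple[float, float, float]:
    """Least-squares two-segment continuous fit with hinge at ``bp``."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(x - bp, 0.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid), float(coef[1]), float(coef[1] + coef[2])


def fit_badl_breakpoint(duration_min: Sequence[float], surface_min: Sequence[float],
                        bin_width: float = 1.0, min_bins: int = 6,
                        min_per_bin: int = 5, sse_reduction: float = 0.10,
                        extended_cutoff: Optional[float] = None) -> BreakpointFit:
    """Behavioral-ADL breakpoint on the surface-vs-dive-duration relation.

    Durations are binned (``bin_width`` min); the per-bin median surface
    duration is fit by every candidate two-segment continuous piecewise-linear
    model with the breakpoint at an interior bin edge.  The minimum-SSE
    candidate is reported only when it reduces SSE by at least
    ``sse_reduction`` relative to a single line and its upper slope is
    steeper; otherwise no behavioral ADL is declared.
    """
    d = np.asarray(duration_min, dtype=float)
    s = np.asarray(surface_min, dtype=float)
    if extended_cutoff is not None:
        keep = s <= extended_cutoff
        d, s = d[keep], s[keep]
    if len(d) < 100:
        return BreakpointFit(None, np.nan, np.nan, np.nan, np.nan, 0,
                             note=f"only {len(d)} dives (< 100)")

    bins = np.floor(d / bin_width).astype(int)
    order = np.argsort(bins, kind="stable")
    uniq, start = np.unique(bins[order], return_index=True)
    med, centers = [], []
    for k, u in enumerate(uniq):
        stop = start[k + 1] if k + 1 < len(uniq) else len(d)
        grp = s[order[start[k]:stop]]
        if len(grp) >= min_per_bin:
            med.append(np.median(grp))
            centers.append((u + 0.5) * bin_width)
    x = np.asarray(centers)
    y = np.asarray(med)
    if len(x) < min_bins:
        return BreakpointFit(None, np.nan, np.nan, np.nan, np.nan, len(x),
                             note=f"only {len(x)} usable bins (< {min_bins})")

    X1 = np.column_stack([np.ones_like(x), x])
    coef1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    r1 = y - X1 @ coef1
    sse1 = float(r1 @ r1)

    best = None
    for bp in np.arange(np.floor(x[0] / bin_width) + 1,
                        np.floor(x[-1] / bin_width) + 1) * bin_width:
        if not (x[0] < bp < x[-1]):
            continue
        sse, lo, hi = _piecewise_sse(x, y, float(bp))
        if best is None or sse < best[0]:
            best = (sse, float(bp), lo, hi)
    if best is None:
        return BreakpointFit(None, float(coef1[1]), float(coef1[1]), sse1, sse1,
                             len(x), note="no interior candidate breakpoints")

    sse2, bp, lo, hi = best
    improvement = (sse1 - sse2) / sse1 if sse1 > 0 else 0.0
    if improvement < sse_reduction or hi <= lo:
        return BreakpointFit(None, float(coef1[1]), float(coef1[1]), sse1, sse1,
                             len(x), note="no detectable behavioral ADL")
    return BreakpointFit(bp, lo, hi, sse2, sse1, len(x))


def flag_extended_surfaces(surface_min: Sequence[float],
                           cutoff: float = 3.5) -> tuple[float, np.ndarray]:
    """Fraction and flags of extended post-dive surface intervals (> cutoff min)."""
    s = np.asarray(surface_min, dtype=float)
    flags = s > cutoff
    frac = float(flags.mean()) if len(s) else np.nan
    return frac, flags


def _binned_median_slope(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """OLS slope through quantile-binned medians of y on x."""
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 3:
        return np.nan
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    bx, by = [], []
    for b in range(len(edges) - 1):
        m = idx == b
        if m.sum() >= 3:
            bx.append(np.median(x[m]))
            by.append(np.median(y[m]))
    if len(bx) < 3:
        return np.nan
    bx, by = np.asarray(bx), np.asarray(by)
    X = np.column_stack([np.ones_like(bx), bx])
    coef, *_ = np.linalg.lstsq(X, by, rcond=None)
    return float(coef[1])


def surface_relations(dives: pd.DataFrame, predictors: Sequence[str] = (
        "duration_min", "total_effort", "bottom_prca_rate"),
        n_boot: int = 1000, seed: int = 0,
        extended_cutoff: float = 3.5) -> pd.DataFrame:
    """Slopes of surface duration against dive metrics, per age class.

    ``dives`` needs ``age_class``, ``surface_min`` and the predictor columns.
    Extended surfaces are excluded; slopes are binned-median OLS with
    seeded bootstrap percentile CIs (``n_boot`` resamples of dives).
    """
    rows = []
    for age, g in dives.groupby("age_class", sort=True):
        keep = g["surface_min"].to_numpy(dtype=float) <= extended_cutoff
        g = g.loc[keep]
        y = g["surface_min"].to_numpy(dtype=float)
        for pred in predictors:
            x = g[pred].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            xo, yo = x[ok], y[ok]
            if len(xo) < 30 or np.ptp(xo) == 0.0:
                rows.append({"age_class": age, "predictor": pred, "slope": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan, "n": len(xo)})
                continue
            slope = _binned_median_slope(xo, yo)
            rng = np.random.Generator(np.random.PCG64(seed))
            boots = np.empty(n_boot)
            for b in range(n_boot):
                ii = rng.integers(0, len(xo), len(xo))
                boots[b] = _binned_median_slope(xo[ii], yo[ii])
            boots = boots[np.isfinite(boots)]
            lo, hi = (np.percentile(boots, [2.5, 97.5]) if len(boots)
                      else (np.nan, np.nan))
            rows.append({"age_class": age, "predictor": pred, "slope": slope,
                         "ci_lo": float(lo), "ci_hi": float(hi), "n": len(xo)})
    return pd.DataFrame(rows)
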