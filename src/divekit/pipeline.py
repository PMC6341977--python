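"""End-to-end orchestration: simulate → abstract → drift → condition → ADL.

``run_pipeline`` streams individuals (profiles are abstracted and discarded
one individual at a time), then aggregates every cohort statistic the study
chain produces into a single structured report: dive durations, surface
durations, depth ontogeny anchors, buoyancy-switch days, initial drift rates,
tADL exceedance proportions, extended-surface fraction, behavioral-ADL
breakpoint, surface-duration relations, departure-phase slopes, BMI and
drift-filter drop counts.  Each statistic carries mean, SD and n.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as dkio
from .abstraction import abstract_cohort, dive_metrics
from .adl import fit_badl_breakpoint, flag_extended_surfaces, surface_relations, tadl_exceedance
from .drift import ConditionSeries, FilterCounts, daily_drift_series, drift_table
from .params import PipelineConfig
from .simulate import iter_cohort
from .trajectory import InsufficientDataError, TripPhases, compute_bmi, departure_slope, segment_phases

__all__ = ["run_pipeline", "report_text"]

_SEED_MASK = 0x7FFFFFFF


def _stat(values, n: Optional[int] = None) -> dict:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        return {"mean": None, "sd": None, "n": 0}
    return {"mean": float(v.mean()),
            "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            "n": int(n if n is not None else len(v))}


def _cohort_seeds(master: int) -> tuple[int, int]:
    state = np.random.SeedSequence(master).generate_state(2)
    return int(state[0]) & _SEED_MASK, int(state[1]) & _SEED_MASK


def _phases_for(ind: str, series: ConditionSeries, config: PipelineConfig) -> TripPhases:
    if config.phase_mode == "detected":
        try:
            return segment_phases(series, config.phase3_decline_threshold)
        except InsufficientDataError:
            pass
    # fixed boundaries; the switch is still the recovery crossing, if any
    switch = None
    s = series.smoothed.dropna()
    if len(s):
        pos = s.loc[(s.index > config.fixed_phase1_end) & (s > 0)]
        if len(pos):
            switch = float(pos.index[0])
    return TripPhases(ind, config.fixed_phase1_end, config.fixed_phase2_end, switch)


def _run_cohort(params, config: PipelineConfig, out_dir: Optional[Path]) -> dict:
    counts = FilterCounts()
    metric_rows, drift_frames, morph_rows = [], [], []
    series_by_ind: dict[str, ConditionSeries] = {}
    phases_by_ind: dict[str, TripPhases] = {}
    truth_by_ind: dict[str, dict] = {}
    duration_daily: dict[str, pd.Series] = {}
    haul_rows = []
    all_summaries = [] if out_dir is not None else None

    for rec in iter_cohort(params):
        _, _, summaries = abstract_cohort([rec])
        for s in summaries:
            metric_rows.append(dive_metrics(s) | {"age_class": s.age_class})
        est = drift_table(summaries, config.filters, counts)
        series = daily_drift_series(est, rec.individual_id,
                                    config.smoothing_window, config.smoothing_min_obs)
        series_by_ind[rec.individual_id] = series
        if params.age_class == "juvenile":
            phases_by_ind[rec.individual_id] = _phases_for(rec.individual_id, series, config)
        drift_frames.append(est)
        morph_rows.append({"individual_id": rec.individual_id,
                           "mass_kg": rec.mass_kg, "length_cm": rec.length_cm})
        t = rec.truth
        truth_by_ind[rec.individual_id] = {
            "switch_day": t.switch_day, "phase1_end": t.phase1_end,
            "phase2_end": t.phase2_end, "trip_end_day": t.trip_end_day,
            "tag_failure_day": t.tag_failure_day}
        if summaries:
            md = pd.DataFrame([{"day": math.floor(s.day), "dur": s.duration / 60.0}
                               for s in summaries])
            duration_daily[rec.individual_id] = md.groupby("day")["dur"].mean()
        for a, b in rec.haul_outs:
            final_dr = float(t.trajectory(t.trip_end_day))
            haul_rows.append({"individual_id": rec.individual_id,
                              "duration_days": b - a, "final_dr": final_dr})
        if all_summaries is not None:
            all_summaries.extend(summaries)

    dives = pd.DataFrame(metric_rows)
    drift = (pd.concat(drift_frames, ignore_index=True) if drift_frames
             else pd.DataFrame(columns=["individual_id", "dive_id", "day",
                                        "drift_rate", "fraction"]))
    morph = pd.DataFrame(morph_rows)
    stats: dict = {"n_individuals": params.n_individuals, "n_dives": int(len(dives)),
                   "n_drift_estimates": int(len(drift)),
                   "filter_counts": counts.as_dict()}
    if len(dives) == 0:
        return {"stats": stats, "series": series_by_ind, "phases": phases_by_ind,
                "truth": truth_by_ind, "dives": dives, "drift": drift}

    # cohort dive statistics
    stats["dive_duration_min"] = _stat(dives["duration_min"])
    per_ind_surf = dives.groupby("individual_id")["surface_min"].mean()
    stats["surface_min_per_individual"] = _stat(per_ind_surf)
    stats["max_depth_m"] = _stat(dives["max_depth_m"])
    frac_ext, _ = flag_extended_surfaces(dives["surface_min"],
                                         config.extended_surface_cutoff)
    stats["extended_surface_frac"] = {"mean": frac_ext, "sd": None,
                                      "n": int(len(dives))}

    if params.age_class == "juvenile":
        d50 = dives.loc[dives["day"].between(47, 53), "max_depth_m"]
        stats["depth_day50_m"] = _stat(d50)
        m8 = dives.loc[dives["day"].between(225, 255), "max_depth_m"]
        stats["depth_month8_m"] = _stat(m8)

        switches = [p.switch_day for p in phases_by_ind.values()
                    if p.switch_day is not None]
        stats["switch_day_detected"] = _stat(switches)
        true_sw = [t["switch_day"] for t in truth_by_ind.values()
                   if t["switch_day"] is not None]
        stats["switch_day_true"] = _stat(true_sw)

        # initial drift rate of individuals departing positively buoyant
        init_rates = []
        for ind, series in series_by_ind.items():
            s = series.smoothed.dropna()
            if len(s) == 0 or s.iloc[0] <= 0:
                continue
            early = drift.loc[(drift["individual_id"] == ind) & (drift["day"] <= 5.0),
                              "drift_rate"]
            if len(early):
                init_rates.append(float(early.mean()))
        stats["initial_drift_rate"] = _stat(init_rates)

        # departure-phase slopes (drift rate and dive duration) per individual
        slope_rows = []
        for ind, series in series_by_ind.items():
            ph = phases_by_ind[ind]
            rec_s = departure_slope(series.daily, ph, "drift_rate")
            if rec_s is not None:
                slope_rows.append({"individual_id": ind, "variable": "drift_rate",
                                   "intercept": rec_s.intercept, "slope": rec_s.slope,
                                   "n_days": rec_s.n_days})
            if ind in duration_daily:
                rec_d = departure_slope(duration_daily[ind], ph, "dive_duration")
                if rec_d is not None:
                    slope_rows.append({"individual_id": ind, "variable": "dive_duration",
                                       "intercept": rec_d.intercept, "slope": rec_d.slope,
                                       "n_days": rec_d.n_days})
        slopes = pd.DataFrame(slope_rows)
        if len(slopes):
            dr_sl = slopes[slopes["variable"] == "drift_rate"]
            stats["departure_dr_slope"] = _stat(dr_sl["slope"])
            stats["departure_duration_slope"] = _stat(
                slopes.loc[slopes["variable"] == "dive_duration", "slope"])
            if len(dr_sl) >= 3 and dr_sl["intercept"].std() > 0:
                r = float(np.corrcoef(dr_sl["intercept"], dr_sl["slope"])[0, 1])
                stats["corr_initial_dr_vs_slope"] = {"mean": r, "sd": None,
                                                     "n": int(len(dr_sl))}
        stats["_slopes_table"] = slopes

        if len(haul_rows):
            hdf = pd.DataFrame(haul_rows)
            stats["haulout_days_positive"] = _stat(hdf.loc[hdf["final_dr"] > 0,
                                                           "duration_days"])
            stats["haulout_days_negative"] = _stat(hdf.loc[hdf["final_dr"] <= 0,
                                                           "duration_days"])

    # tADL exceedance
    adl_input = dives.rename(columns={"duration_min": "_dur"}).assign(
        duration_s=lambda d: d["_dur"] * 60.0)
    per_ind_adl, pooled_adl = tadl_exceedance(
        adl_input, phases_by_ind if params.age_class == "juvenile" else None,
        config.tadl)
    stats["tadl"] = {row["phase"]: {"mean": row["mean"],
                                    "sd": None if pd.isna(row["sd"]) else row["sd"],
                                    "n": int(row["n"])}
                     for _, row in pooled_adl.iterrows()}
    stats["_tadl_table"] = per_ind_adl

    # behavioral ADL and surface relations
    bp = fit_badl_breakpoint(dives["duration_min"], dives["surface_min"],
                             bin_width=config.breakpoint_bin_width,
                             extended_cutoff=config.extended_surface_cutoff)
    stats["badl"] = {"breakpoint_min": bp.breakpoint, "slope_below": bp.slope_below,
                     "slope_above": bp.slope_above, "sse": bp.loss,
                     "sse_single_line": bp.loss_single, "n_bins": bp.n_bins,
                     "note": bp.note}
    rel = surface_relations(dives, n_boot=config.bootstrap_resamples,
                            seed=params.seed,
                            extended_cutoff=config.extended_surface_cutoff)
    stats["_surface_relations"] = rel

    # BMI
    if len(morph) >= 3:
        bmi = compute_bmi(morph)
        stats["bmi_sd_kg"] = {"mean": float(bmi["bmi_kg"].std(ddof=1)),
                              "sd": None, "n": int(len(bmi))}
        stats["_bmi_table"] = bmi

    return {"stats": stats, "series": series_by_ind, "phases": phases_by_ind,
            "truth": truth_by_ind, "dives": dives, "drift": drift,
            "summaries": all_summaries}


def _clean_stats(stats: dict) -> dict:
    return {k: v for k, v in stats.items() if not k.startswith("_")}


def run_pipeline(config: PipelineConfig, out_dir: Optional[str | Path] = None,
                 cohorts: tuple[str, ...] = ("juvenile", "adult")) -> dict:
    """Run the full chain for the configured cohorts and build the report.

    With ``out_dir`` set, per-stage CSV outputs (drift.csv, phases.csv,
    slopes.csv, bmi.csv, tadl.csv, surface_relations.csv, badl.json) and the
    report (JSON + text) are written there.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    juv_seed, adult_seed = _cohort_seeds(config.seed)
    report: dict = {"seed": config.seed, "cohorts": {}}
    for cohort in cohorts:
        params = (config.juvenile.replace(seed=juv_seed) if cohort == "juvenile"
                  else config.adult.replace(seed=adult_seed))
        res = _run_cohort(params, config, out_path)
        report["cohorts"][cohort] = _clean_stats(res["stats"])
        if out_path is not None:
            _write_stage_outputs(cohort, res, out_path)
    if out_path is not None:
        dkio.write_json(_sanitize(report), out_path / "report.json")
        (out_path / "report.txt").write_text(report_text(report))
    return report


def _write_stage_outputs(cohort: str, res: dict, out_path: Path) -> None:
    res["drift"].to_csv(out_path / f"drift_{cohort}.csv", index=False)
    stats = res["stats"]
    phase_rows = [{"individual_id": k, "phase1_end": p.phase1_end,
                   "phase2_end": p.phase2_end, "switch_day": p.switch_day}
                  for k, p in res["phases"].items()]
    pd.DataFrame(phase_rows, columns=["individual_id", "phase1_end",
                                      "phase2_end", "switch_day"]
                 ).to_csv(out_path / f"phases_{cohort}.csv", index=False)
    for key, name in (("_slopes_table", "slopes"), ("_bmi_table", "bmi"),
                      ("_tadl_table", "tadl"), ("_surface_relations",
                                                "surface_relations")):
        if key in stats:
            stats[key].to_csv(out_path / f"{name}_{cohort}.csv", index=False)
    if stats.get("badl") is not None:
        dkio.write_json(_sanitize(stats["badl"]), out_path / f"badl_{cohort}.json")
    if res.get("summaries"):
        dkio.write_abstracted(res["summaries"],
                              out_path / f"dives_abstracted_{cohort}.csv")


def _sanitize(obj):
    """NaN → null and numpy scalars → python, recursively."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return None if not math.isfinite(f) else f
    return obj


def report_text(report: dict) -> str:
    """Human-readable rendering of the pipeline report."""
    lines = [f"divekit pipeline report (seed {report.get('seed')})", ""]
    for cohort, stats in report.get("cohorts", {}).items():
        lines.append(f"[{cohort}]  individuals={stats.get('n_individuals')}  "
                     f"dives={stats.get('n_dives')}  "
                     f"drift estimates={stats.get('n_drift_estimates')}")
        for key, val in stats.items():
            if key in ("n_individuals", "n_dives", "n_drift_estimates"):
                continue
            if isinstance(val, dict) and "mean" in val:
                m, sd, n = val.get("mean"), val.get("sd"), val.get("n")
                ms = "missing" if m is None else f"{m:.4g}"
                ss = "" if sd in (None, 0.0) else f" ± {sd:.3g}"
                lines.append(f"  {key}: {ms}{ss} (n={n})")
            elif key == "tadl":
                for ph, v in val.items():
                    m = v.get("mean")
                    ms = "missing" if m is None else f"{100 * m:.1f}%"
                    lines.append(f"  tadl[{ph}]: {ms} (n={v.get('n')})")
            elif key == "badl":
                bpv = val.get("breakpoint_min")
                lines.append(f"  badl breakpoint: "
                             f"{'none' if bpv is None else f'{bpv:.1f} min'}"
                             f" ({val.get('note') or 'detected'})")
            elif key == "filter_counts":
                lines.append(f"  drift filter drops: {val}")
        lines.append("")
    return "\n".join(lines) + "\n"
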