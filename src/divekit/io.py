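"""CSV readers/writers for the pipeline's table schemas.

All files are comma-delimited, UTF-8, '.' decimal, with a header row.  Raw
cohort exports follow the tag-data layout (dives / profiles / accel segments /
morphometrics, plus generating truth for synthetic cohorts); abstracted dives
round-trip through a single two-level CSV (one row per dive plus one per
segment, distinguished by a ``record`` column).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from .abstraction import DiveSegment, DiveSummary
from .simulate import AccelSegment, DepthSeries, TripRecord

__all__ = [
    "write_cohort",
    "read_raw_dives",
    "read_morphometrics",
    "read_truth_daily",
    "write_abstracted",
    "read_abstracted",
    "write_json",
]


def write_cohort(records: Iterable[TripRecord], outdir: str | Path,
                 write_profiles: bool = True) -> None:
    """Write a cohort to dives/profiles/segments_accel/morphometrics/truth CSVs.

    Full-cohort 1-Hz profiles are large; pass ``write_profiles=False`` to
    skip ``profiles.csv`` when only the abstracted chain is needed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dive_rows, accel_rows, morph_rows, truth_rows, haul_rows = [], [], [], [], []
    prof_path = outdir / "profiles.csv"
    prof_file = open(prof_path, "w", encoding="utf-8") if write_profiles else None
    if prof_file:
        prof_file.write("dive_id,t_offset_s,depth_m\n")
    try:
        for rec in records:
            morph_rows.append({"individual_id": rec.individual_id,
                               "age_class": rec.age_class, "mass_kg": rec.mass_kg,
                               "length_cm": rec.length_cm,
                               "departure_day": rec.departure_day})
            for k, d in enumerate(rec.dives):
                dive_id = f"{rec.individual_id}_{k:05d}"
                dive_rows.append({"dive_id": dive_id,
                                  "individual_id": rec.individual_id,
                                  "day": d.day, "t0_s": d.profile.t0_s,
                                  "duration_s": d.profile.duration_s,
                                  "surface_s": d.surface_s})
                for j, seg in enumerate(d.accel):
                    accel_rows.append({"dive_id": dive_id, "segment_idx": j,
                                       "t_start_s": seg.t_start, "t_end_s": seg.t_end,
                                       "effort_sum": seg.effort_sum,
                                       "prca_s": seg.prca_s})
                if prof_file:
                    depth = d.profile.depth
                    lines = [f"{dive_id},{t},{z:.3f}" for t, z in enumerate(depth)]
                    prof_file.write("\n".join(lines) + "\n")
            truth = rec.truth
            days = np.arange(int(np.ceil(truth.trip_end_day)) + 1)
            dr = truth.trajectory(days)
            for day, v in zip(days, dr):
                truth_rows.append({
                    "individual_id": rec.individual_id, "day": int(day),
                    "dr_true": float(v),
                    "switch_day": truth.switch_day,
                    "phase1_end": truth.phase1_end, "phase2_end": truth.phase2_end,
                    "trip_end_day": truth.trip_end_day,
                    "tag_failure_day": truth.tag_failure_day})
            for (a, b) in rec.haul_outs:
                haul_rows.append({"individual_id": rec.individual_id,
                                  "start_day": a, "end_day": b})
    finally:
        if prof_file:
            prof_file.close()
    pd.DataFrame(dive_rows).to_csv(outdir / "dives.csv", index=False)
    pd.DataFrame(accel_rows).to_csv(outdir / "segments_accel.csv", index=False)
    pd.DataFrame(morph_rows).to_csv(outdir / "morphometrics.csv", index=False)
    pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
    pd.DataFrame(haul_rows, columns=["individual_id", "start_day", "end_day"]
                 ).to_csv(outdir / "haul_outs.csv", index=False)


def read_raw_dives(indir: str | Path) -> Iterator[tuple[dict, DepthSeries, list[AccelSegment]]]:
    """Iterate raw dives from a cohort directory written by :func:`write_cohort`.

    Yields ``(dive_row, profile, accel_segments)`` per dive.  Requires
    ``profiles.csv`` to be present.
    """
    indir = Path(indir)
    dives = pd.read_csv(indir / "dives.csv")
    accel = pd.read_csv(indir / "segments_accel.csv")
    profiles = pd.read_csv(indir / "profiles.csv")
    accel_g = {k: v for k, v in accel.groupby("dive_id", sort=False)}
    prof_g = {k: v for k, v in profiles.groupby("dive_id", sort=False)}
    for _, row in dives.iterrows():
        did = row["dive_id"]
        prof = prof_g.get(did)
        if prof is None:
            continue
        depth = prof.sort_values("t_offset_s")["depth_m"].to_numpy(dtype=float)
        segs = [AccelSegment(r["t_start_s"], r["t_end_s"], r["effort_sum"], r["prca_s"])
                for _, r in accel_g.get(did, pd.DataFrame(
                    columns=["t_start_s", "t_end_s", "effort_sum", "prca_s"])).iterrows()]
        yield dict(row), DepthSeries(float(row["t0_s"]), depth), segs


def read_morphometrics(indir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "morphometrics.csv")


def read_truth_daily(indir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(indir) / "truth.csv")


_DIVE_COLS = ["record", "dive_id", "individual_id", "age_class", "day",
              "duration_s", "surface_s", "max_depth_m", "segment_idx", "role",
              "t_start_s", "t_end_s", "depth_start_m", "depth_end_m",
              "vertical_rate", "effort_sum", "prca_fraction"]


def write_abstracted(summaries: Iterable[DiveSummary], path: str | Path) -> None:
    """One row per dive plus one row per segment, in a single CSV."""
    rows = []
    for s in summaries:
        rows.append({"record": "dive", "dive_id": s.dive_id,
                     "individual_id": s.individual_id, "age_class": s.age_class,
                     "day": s.day, "duration_s": s.duration,
                     "surface_s": s.surface_duration, "max_depth_m": s.max_depth})
        for seg in s.segments:
            rows.append({"record": "segment", "dive_id": s.dive_id,
                         "individual_id": s.individual_id,
                         "segment_idx": seg.segment_idx, "role": seg.role,
                         "t_start_s": seg.t_start, "t_end_s": seg.t_end,
                         "depth_start_m": seg.depth_start,
                         "depth_end_m": seg.depth_end,
                         "vertical_rate": seg.vertical_rate,
                         "effort_sum": seg.effort_sum,
                         "prca_fraction": seg.prca_fraction})
    pd.DataFrame(rows, columns=_DIVE_COLS).to_csv(path, index=False,
                                                  float_format="%.10g")


def read_abstracted(path: str | Path) -> list[DiveSummary]:
    df = pd.read_csv(path)
    missing = set(_DIVE_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: abstracted-dive file missing columns {sorted(missing)}")
    out: list[DiveSummary] = []
    seg_g = {k: v for k, v in df[df["record"] == "segment"].groupby("dive_id", sort=False)}
    for _, row in df[df["record"] == "dive"].iterrows():
        segs = []
        for _, r in seg_g.get(row["dive_id"], pd.DataFrame(columns=df.columns)).iterrows():
            dur = r["t_end_s"] - r["t_start_s"]
            segs.append(DiveSegment(
                segment_idx=int(r["segment_idx"]), t_start=r["t_start_s"],
                t_end=r["t_end_s"], depth_start=r["depth_start_m"],
                depth_end=r["depth_end_m"], vertical_rate=r["vertical_rate"],
                effort_sum=r["effort_sum"], effort_rate=r["effort_sum"] / dur,
                prca_fraction=r["prca_fraction"], role=str(r["role"])))
        out.append(DiveSummary(
            dive_id=str(row["dive_id"]), individual_id=str(row["individual_id"]),
            day=float(row["day"]), max_depth=float(row["max_depth_m"]),
            duration=float(row["duration_s"]), surface_duration=float(row["surface_s"]),
            segments=segs, age_class=str(row["age_class"])))
    return out


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=False, default=_json_default) + "\n")


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
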