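"""Parameter blocks for simulation, filtering and pipeline orchestration.

Defaults encode the study conditions of a first-year southern elephant seal
cohort: 20 juveniles tagged with satellite-relayed dive/accelerometer loggers
sampling one dive every 2 h for up to ~338 days, and 9 post-breeding adult
females recorded continuously for ~2–3 months.  All durations are minutes at
this configuration boundary; the simulation and analysis core work in seconds
and meters throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "GeneratorParams",
    "FilterThresholds",
    "TADLThresholds",
    "PipelineConfig",
    "juvenile_defaults",
    "adult_defaults",
]


@dataclass
class GeneratorParams:
    """Parametric behavioral model for one simulated cohort.

    A cohort is homogeneous in age class; juvenile and adult presets are
    provided by :func:`juvenile_defaults` and :func:`adult_defaults`.
    """

    # cohort
    n_individuals: int = 20
    age_class: str = "juvenile"           # {"juvenile", "adult"}
    trip_days_max: float = 338.0
    dive_interval: Optional[float] = 2.0  # hours between recorded dives; None = continuous
    seed: int = 0

    # depth ontogeny (m). Juvenile mean depth is linear through
    # (50 d, depth_mean_day50) and (240 d, depth_mean_month8), constant after
    # 240 d; adults dive at a stationary adult_depth_mean.
    depth_mean_day50: float = 115.0
    depth_mean_month8: float = 227.0
    adult_depth_mean: float = 474.0
    depth_cv: float = 0.18
    depth_min: float = 25.0
    depth_max: float = 700.0

    # dive duration (min). Juvenile mean ramps from dive_dur_day0_mean at
    # departure to dive_dur_mean over dur_ramp_days; adults are stationary.
    dive_dur_mean: float = 14.0
    dive_dur_day0_mean: float = 8.0
    dur_ramp_days: float = 100.0
    dive_dur_sd: float = 5.0
    dive_dur_min: float = 2.0
    dive_dur_max: float = 34.7

    # post-dive surface interval (min)
    surf_base: float = 0.86
    surf_effort_coef: float = 2.0e-4      # min per unit summed lateral acceleration
    surf_prca_coef: float = 0.3           # min per unit bottom PrCA rate
    surf_noise_sd: float = 0.08
    surf_floor: float = 0.5
    extended_surf_prob: float = 0.013
    extended_surf_min: float = 3.5
    extended_surf_exp_mean: float = 1.5   # mean of the exponential tail past the cutoff

    # drift dives
    drift_dive_prob: float = 0.10
    drift_noise_sd: float = 0.01          # m/s noise on the passive vertical rate
    drift_min_start_depth: float = 80.0   # passive phase begins below this depth
    drift_frac_target: float = 0.47       # lower bound on drift fraction of dive time

    # drift-rate (body condition) trajectory, m/s upward-positive
    dr_init_mean: float = 0.15
    dr_init_sd: float = 0.04
    dr_init_neg_mean: float = -0.21
    dr_init_neg_sd: float = 0.02
    positive_init_frac: float = 0.85
    dr_trough_mean: float = -0.22
    dr_trough_sd: float = 0.03
    dr_phase1_end: float = 50.0
    dr_switch_day_mean: float = 93.0
    dr_switch_day_sd: float = 15.0
    switch_frac: float = 0.45
    peak_margin_days: float = 25.0        # days from zero-crossing to the phase-2 peak
    phase3_slope_min: float = 0.001       # m/s per day, post-peak decline
    phase3_slope_max: float = 0.002
    dr_adult_final_mean: float = -0.08    # adults improve but stay negative
    dr_adult_final_sd: float = 0.02

    # trip end / attrition
    return_dur_mean: float = 45.0         # days from buoyancy switch to haul-out
    return_dur_sd: float = 10.0
    early_fail_frac: float = 0.40         # fraction of tags lost before day ~100
    early_fail_day_min: float = 20.0
    early_fail_day_max: float = 100.0

    # swimming effort (lateral-axis acceleration summed per segment; rates m/s^3)
    effort_neutral_min: float = 5.5
    effort_buoyancy_coef: float = 3.0     # m/s^3 per |m/s| deviation from neutral buoyancy
    effort_noise_sd: float = 0.4
    drift_effort_lo: float = 0.3          # passive-segment effort rate band, m/s^3
    drift_effort_hi: float = 2.5

    # prey catch attempts (fraction of bottom time)
    prca_juv_scale: float = 0.10
    prca_adult_scale: float = 0.10
    prca_sd: float = 0.05
    prca_ontogeny_gain: float = 1.2       # juvenile excess at departure, decays to 0 by day 100

    # vertical transit rates (m/s)
    descent_rate_min: float = 1.0
    descent_rate_max: float = 1.5

    # dive geometry
    bottom_wiggle_sd: float = 1.5         # m, foraging excursions above max depth

    # morphometrics
    mass_mean: float = 80.0
    mass_sd: float = 18.0
    length_mean: float = 139.0
    length_sd: float = 11.0
    mass_length_corr: float = 0.7

    # haul-outs keyed to buoyancy sign at return (days)
    haulout_pos_mean: float = 8.7
    haulout_pos_sd: float = 4.4
    haulout_neg_mean: float = 2.9
    haulout_neg_sd: float = 2.59

    def __post_init__(self) -> None:
        for name in ("drift_dive_prob", "extended_surf_prob", "positive_init_frac",
                     "switch_frac", "early_fail_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("dive_dur_sd", "dr_init_sd", "dr_switch_day_sd", "surf_noise_sd",
                     "drift_noise_sd", "mass_sd", "length_sd", "prca_sd", "dr_trough_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dive_interval is not None and self.dive_interval <= 0:
            raise ValueError("dive_interval must be > 0 hours (or None for continuous)")
        if self.age_class not in ("juvenile", "adult"):
            raise ValueError(f"age_class must be 'juvenile' or 'adult', got {self.age_class!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")

    def replace(self, **kwargs) -> "GeneratorParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown generator parameter(s): {sorted(unknown)}")
        return cls(**d)


def juvenile_defaults(**overrides) -> GeneratorParams:
    """Default juvenile cohort: n=20, one recorded dive per 2 h, up to 338 days."""
    return GeneratorParams(**overrides) if overrides else GeneratorParams()


def adult_defaults(**overrides) -> GeneratorParams:
    """Default post-breeding adult-female cohort: n=9, continuous records, ~70 days."""
    base = dict(
        n_individuals=9,
        age_class="adult",
        trip_days_max=70.0,
        dive_interval=None,
        dive_dur_mean=18.5,
        dive_dur_day0_mean=18.5,
        dur_ramp_days=0.0,
        dive_dur_sd=5.0,
        dive_dur_max=40.0,
        depth_cv=0.17,
        surf_base=1.44,
        surf_effort_coef=1.2e-4,
        dr_init_mean=-0.25,
        dr_init_sd=0.02,
        early_fail_frac=0.0,
        mass_mean=267.0,
        mass_sd=60.0,
        length_mean=257.0,
        length_sd=38.0,
    )
    base.update(overrides)
    return GeneratorParams(**base)


@dataclass
class FilterThresholds:
    """Thresholds of the five-step drift-segment filter."""

    effort_max: float = 4.0        # m/s^3; bimodal effort split between active and passive
    speed_min: float = -0.3        # m/s, below = unrealistic sinking
    speed_max: float = 0.6         # m/s, above = unrealistic rising
    min_fraction: float = 0.40     # of total dive duration
    null_tol: float = 1e-6         # |rate| below this = resting on the sea floor
    speed_before_fraction: bool = True  # apply the speed filter before the 40% filter
    min_drift_depth: Optional[float] = None  # optional: segment must start below this (m)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterThresholds":
        return cls(**d)


@dataclass
class TADLThresholds:
    """Theoretical aerobic-dive-limit thresholds (minutes) per trip phase."""

    departure: float = 6.0
    central: float = 10.0
    return_: float = 18.0
    adult: float = 28.0

    def __post_init__(self) -> None:
        if not self.departure < self.central < self.return_:
            raise ValueError("juvenile tADL thresholds must increase across phases")

    def to_dict(self) -> dict:
        return {"departure": self.departure, "central": self.central,
                "return": self.return_, "adult": self.adult}

    @classmethod
    def from_dict(cls, d: dict) -> "TADLThresholds":
        d = dict(d)
        if "return" in d:
            d["return_"] = d.pop("return")
        return cls(**d)


@dataclass
class PipelineConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    juvenile: GeneratorParams = field(default_factory=juvenile_defaults)
    adult: GeneratorParams = field(default_factory=adult_defaults)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    tadl: TADLThresholds = field(default_factory=TADLThresholds)
    smoothing_window: int = 7      # days, centered rolling median
    smoothing_min_obs: int = 3
    phase_mode: str = "detected"   # {"detected", "fixed"}
    fixed_phase1_end: float = 50.0
    fixed_phase2_end: float = 100.0
    phase3_decline_threshold: float = 0.02  # m/s drop needed to declare a return phase
    extended_surface_cutoff: float = 3.5    # min
    breakpoint_bin_width: float = 1.0       # min
    bootstrap_resamples: int = 1000
    seed: int = 1
    write_profiles: bool = False

    def __post_init__(self) -> None:
        if self.phase_mode not in ("detected", "fixed"):
            raise ValueError("phase_mode must be 'detected' or 'fixed'")
        if self.smoothing_window < 1 or self.smoothing_min_obs < 1:
            raise ValueError("smoothing window and min observations must be >= 1")

    def to_dict(self) -> dict:
        return {
            "juvenile": self.juvenile.to_dict(),
            "adult": self.adult.to_dict(),
            "filters": self.filters.to_dict(),
            "tadl": self.tadl.to_dict(),
            "smoothing_window": self.smoothing_window,
            "smoothing_min_obs": self.smoothing_min_obs,
            "phase_mode": self.phase_mode,
            "fixed_phase1_end": self.fixed_phase1_end,
            "fixed_phase2_end": self.fixed_phase2_end,
            "phase3_decline_threshold": self.phase3_decline_threshold,
            "extended_surface_cutoff": self.extended_surface_cutoff,
            "breakpoint_bin_width": self.breakpoint_bin_width,
            "bootstrap_resamples": self.bootstrap_resamples,
            "seed": self.seed,
            "write_profiles": self.write_profiles,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kwargs = {}
        if "juvenile" in d:
            kwargs["juvenile"] = GeneratorParams.from_dict(d.pop("juvenile"))
        if "adult" in d:
            kwargs["adult"] = GeneratorParams.from_dict(d.pop("adult"))
        if "filters" in d:
            kwargs["filters"] = FilterThresholds.from_dict(d.pop("filters"))
        if "tadl" in d:
            kwargs["tadl"] = TADLThresholds.from_dict(d.pop("tadl"))
        kwargs.update(d)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
        return cls.from_dict(data)
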