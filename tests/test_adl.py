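"""tADL exceedance, behavioral-ADL breakpoint, extended surfaces, relations."""

import numpy as np
import pandas as pd
import pytest

import divekit as dk
from divekit.abstraction import abstract_cohort, dive_metrics
from divekit.adl import (fit_badl_breakpoint, flag_extended_surfaces,
                         surface_relations, tadl_exceedance)
from divekit.params import TADLThresholds
from divekit.trajectory import TripPhases


def _dives(durs_min, individual="a", age="juvenile", days=None):
    days = days if days is not None else np.zeros(len(durs_min))
    return pd.DataFrame({"individual_id": individual, "age_class": age,
                         "day": days, "duration_s": np.asarray(durs_min) * 60.0})


class TestTADL:
    def test_half_exceed(self):
        phases = {"a": TripPhases("a", 50.0, None, None)}
        per_ind, pooled = tadl_exceedance(_dives([5.0, 7.0]), phases)
        assert per_ind.loc[0, "proportion"] == 0.5
        assert pooled.loc[0, "mean"] == 0.5

    def test_all_below_threshold(self):
        phases = {"a": TripPhases("a", 50.0, None, None)}
        _, pooled = tadl_exceedance(_dives([2.0, 3.0, 5.9]), phases)
        assert pooled.loc[0, "mean"] == 0.0

    def test_phase_assignment_uses_phase_thresholds(self):
        phases = {"a": TripPhases("a", 50.0, 100.0, None)}
        df = _dives([8.0, 8.0, 8.0], days=[10.0, 70.0, 120.0])
        per_ind, _ = tadl_exceedance(df, phases)
        by_phase = dict(zip(per_ind["phase"], per_ind["proportion"]))
        assert by_phase == {"departure": 1.0, "central": 0.0, "return": 0.0}

    def test_adults_use_adult_threshold(self):
        df = _dives([20.0, 30.0], age="adult")
        per_ind, _ = tadl_exceedance(df, None)
        assert per_ind.loc[0, "phase"] == "adult"
        assert per_ind.loc[0, "proportion"] == 0.5

    def test_raising_threshold_never_increases_proportion(self, rng):
        phases = {"a": TripPhases("a", 50.0, None, None)}
        df = _dives(rng.uniform(1, 30, 500))
        props = []
        for thr in (4.0, 6.0, 8.0, 12.0):
            t = TADLThresholds(departure=thr, central=thr + 1, return_=thr + 2)
            _, pooled = tadl_exceedance(df, phases, t)
            props.append(pooled.loc[0, "mean"])
        assert all(a >= b for a, b in zip(props, props[1:]))


class TestBreakpoint:
    def test_exact_piecewise_input(self, rng):
        d = rng.uniform(2, 35, 2000)
        surf = np.where(d <= 20, 1.0, 1.0 + 0.5 * (d - 20))
        fit = fit_badl_breakpoint(d, surf)
        assert fit.breakpoint == pytest.approx(20.0)
        assert fit.slope_above > fit.slope_below

    def test_linear_relation_yields_no_breakpoint(self, rng):
        d = rng.uniform(2, 35, 2000)
        fit = fit_badl_breakpoint(d, 0.5 + 0.1 * d)
        assert fit.breakpoint is None

    def test_nesting_sse(self, rng):
        d = rng.uniform(2, 35, 3000)
        surf = 1.0 + 0.05 * d + rng.normal(0, 0.3, 3000)
        fit = fit_badl_breakpoint(d, surf)
        assert fit.loss <= fit.loss_single + 1e-12

    def test_duplication_invariance(self, rng):
        d = rng.uniform(2, 35, 1500)
        surf = np.where(d <= 22, 1.0, 1.0 + 0.4 * (d - 22)) + rng.normal(0, 0.1, 1500)
        a = fit_badl_breakpoint(d, surf)
        b = fit_badl_breakpoint(np.tile(d, 2), np.tile(surf, 2))
        assert a.breakpoint == b.breakpoint

    def test_too_few_dives_or_bins(self, rng):
        fit = fit_badl_breakpoint([10.0] * 50, [1.0] * 50)
        assert fit.breakpoint is None and "dives" in fit.note
        d = rng.uniform(10, 13, 500)
        fit = fit_badl_breakpoint(d, np.full(500, 1.0))
        assert fit.breakpoint is None and "bins" in fit.note

    def test_extended_surfaces_excluded(self, rng):
        d = rng.uniform(2, 35, 2000)
        surf = 0.5 + 0.02 * d
        surf[d > 30] += 10.0  # extended intervals would fake an inflection
        fit = fit_badl_breakpoint(d, surf, extended_cutoff=3.5)
        assert fit.breakpoint is None


class TestExtendedSurfaces:
    def test_fraction(self):
        frac, flags = flag_extended_surfaces([3.0, 4.0], cutoff=3.5)
        assert frac == 0.5
        assert list(flags) == [False, True]
        frac, _ = flag_extended_surfaces([1.0, 1.0, 1.0])
        assert frac == 0.0


class TestSurfaceRelations:
    @staticmethod
    def _cohort_dives(**overrides):
        params = dk.juvenile_defaults(n_individuals=2, trip_days_max=25.0, seed=31,
                                      **overrides)
        _, _, summaries = abstract_cohort(dk.simulate_cohort(params))
        return pd.DataFrame([dive_metrics(s) | {"age_class": s.age_class}
                             for s in summaries])

    def test_null_effort_coefficient_recovered(self):
        df = self._cohort_dives(surf_effort_coef=0.0, surf_prca_coef=0.0)
        rel = surface_relations(df, predictors=("total_effort",), n_boot=200, seed=5)
        row = rel.iloc[0]
        assert row["ci_lo"] <= 0.0 <= row["ci_hi"]

    def test_signs_recovered_from_generator(self):
        df = self._cohort_dives()
        rel = surface_relations(df, n_boot=200, seed=5).set_index("predictor")
        assert rel.loc["total_effort", "slope"] > 0
        assert rel.loc["bottom_prca_rate", "slope"] < 0

    def test_juvenile_effort_slope_steeper_than_adult(self):
        juv = self._cohort_dives()
        ap = dk.adult_defaults(n_individuals=2, trip_days_max=4.0, seed=32)
        _, _, summ = abstract_cohort(dk.simulate_cohort(ap))
        ad = pd.DataFrame([dive_metrics(s) | {"age_class": s.age_class}
                           for s in summ])
        rel = surface_relations(pd.concat([juv, ad], ignore_index=True),
                                predictors=("total_effort",), n_boot=100, seed=5)
        slopes = dict(zip(rel["age_class"], rel["slope"]))
        assert slopes["juvenile"] > slopes["adult"]
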