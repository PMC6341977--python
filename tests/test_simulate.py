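"""Generator: condition templates, dive construction, cohort contracts."""

import numpy as np
import pytest

import divekit as dk
from divekit.simulate import (ConditionTrajectory, _assign_roles, cohort_checksum,
                              condition_model, draw_condition_trajectory,
                              simulate_dive)


class TestConditionModel:
    def test_day_zero_returns_initial_drift_rate(self, rng):
        params = dk.juvenile_defaults()
        traj, anchors = draw_condition_trajectory(params, rng, positive_init=True,
                                                  switcher=True)
        assert condition_model(0.0, params, traj) == pytest.approx(anchors["dr_init"])
        assert 0.03 <= anchors["dr_init"] <= 0.28

    def test_zero_slopes_give_flat_trajectory(self):
        params = dk.juvenile_defaults()
        flat = ConditionTrajectory([0.0, 338.0], [0.15, 0.15])
        days = np.linspace(0, 338, 50)
        assert np.allclose(condition_model(days, params, flat), 0.15)

    def test_piecewise_linearity_at_phase1_midpoint(self, rng):
        params = dk.juvenile_defaults()
        traj, _ = draw_condition_trajectory(params, rng)
        p1 = params.dr_phase1_end
        mid = condition_model(p1 / 2, params, traj)
        assert mid == pytest.approx((traj(0.0) + traj(p1)) / 2)

    def test_negative_day_rejected(self, rng):
        params = dk.juvenile_defaults()
        traj, _ = draw_condition_trajectory(params, rng)
        with pytest.raises(ValueError):
            condition_model(-1.0, params, traj)

    def test_three_phase_shape(self, rng):
        """Decline to the trough, recovery to the peak, decline after."""
        params = dk.juvenile_defaults()
        for _ in range(20):
            traj, a = draw_condition_trajectory(params, rng, switcher=True)
            days = traj.knot_days
            assert traj(days[0]) > traj(days[1])       # departure decline
            assert traj(days[1]) < traj(days[2])       # central recovery
            assert traj(days[2]) >= traj(days[3])      # return decline
            assert a["switch_day"] is not None
            assert traj(a["switch_day"]) == pytest.approx(0.0, abs=1e-9)

    def test_non_switcher_recovery_peak_stays_negative(self, rng):
        """A non-switcher may depart positively buoyant, but after the
        departure decline it never crosses back above zero."""
        params = dk.juvenile_defaults()
        for _ in range(20):
            traj, a = draw_condition_trajectory(params, rng, switcher=False)
            assert a["switch_day"] is None
            after = np.linspace(params.dr_phase1_end, 338, 300)
            assert traj(after).max() < 0

    def test_adult_trajectory_improves_but_stays_negative(self, rng):
        params = dk.adult_defaults()
        traj, a = draw_condition_trajectory(params, rng)
        days = np.linspace(0, params.trip_days_max, 100)
        vals = traj(days)
        assert np.all(np.diff(vals) >= 0)
        assert vals.max() < 0


class TestSimulateDive:
    def test_noise_free_drift_segment_rate_is_exact(self, rng):
        params = dk.juvenile_defaults(drift_noise_sd=0.0)
        d = simulate_dive(10.0, -0.12, params, rng, force_drift=True)
        assert d.drift_rate_realized == pytest.approx(-0.12, abs=1e-12)

    def test_drift_rate_outside_band_rejected(self, rng):
        params = dk.juvenile_defaults()
        with pytest.raises(ValueError, match="drift band"):
            simulate_dive(10.0, -0.35, params, rng)
        with pytest.raises(ValueError, match="drift band"):
            simulate_dive(10.0, 0.65, params, rng)

    def test_physicality(self, rng):
        params = dk.juvenile_defaults()
        for day in (0.0, 60.0, 200.0):
            d = simulate_dive(day, -0.1, params, rng)
            depth = d.profile.depth
            assert np.all(depth >= 0)
            assert depth[0] < 5 and depth[-1] < 5
            assert d.profile.duration_s == len(depth) - 1
            # true accel segments partition the dive
            edges = [s.t_start for s in d.accel] + [d.accel[-1].t_end]
            assert edges[0] == 0 and edges[-1] == d.profile.duration_s
            assert np.all(np.diff(edges) > 0)

    def test_drift_segment_geometry(self, rng):
        """Passive phase starts below 65 m and fills >= 40% of the dive."""
        params = dk.juvenile_defaults()
        for _ in range(50):
            d = simulate_dive(30.0, rng.uniform(-0.28, 0.28), params, rng,
                              force_drift=True)
            seg = d.accel[1]
            assert d.profile.depth[int(seg.t_start)] >= 65.0
            assert (seg.t_end - seg.t_start) >= 0.40 * d.profile.duration_s
            assert seg.prca_s == 0.0
            assert seg.effort_sum / (seg.t_end - seg.t_start) < 4.0

    def test_surface_duration_floor(self, rng):
        params = dk.juvenile_defaults(surf_base=0.0, surf_effort_coef=0.0,
                                      extended_surf_prob=0.0)
        d = simulate_dive(5.0, -0.1, params, rng)
        assert d.surface_s >= 30.0


class TestCohort:
    def test_single_day_dive_count(self):
        params = dk.juvenile_defaults(n_individuals=1, trip_days_max=1.0, seed=3)
        rec = dk.simulate_cohort(params)[0]
        assert len(rec.dives) == 12  # one recorded dive per 2 h

    def test_determinism_checksum(self):
        params = dk.juvenile_defaults(n_individuals=2, trip_days_max=15.0, seed=5)
        a = cohort_checksum(dk.simulate_cohort(params))
        b = cohort_checksum(dk.simulate_cohort(params))
        c = cohort_checksum(dk.simulate_cohort(params.replace(seed=6)))
        assert a == b
        assert a != c

    def test_growing_cohort_keeps_earlier_individuals(self):
        p2 = dk.juvenile_defaults(n_individuals=2, trip_days_max=10.0, seed=9)
        p3 = p2.replace(n_individuals=3)
        first_two = dk.simulate_cohort(p2)
        first_three = dk.simulate_cohort(p3)
        assert cohort_checksum(first_two) == cohort_checksum(first_three[:2])

    def test_default_role_quotas(self):
        """20 juveniles: 17 initially positive, 9 switchers, 8 early failures."""
        positive, switcher, fail = _assign_roles(dk.juvenile_defaults())
        assert positive.sum() == 17
        assert switcher.sum() == 9
        assert fail.sum() == 8
        assert not np.any(switcher & fail)      # failures among non-switchers

    def test_truth_is_attached_and_consistent(self, small_juvenile_cohort):
        _, records = small_juvenile_cohort
        for rec in records:
            t = rec.truth
            days = np.arange(int(t.trip_end_day))
            dr = t.trajectory(days)
            assert np.all(np.isfinite(dr))
            assert np.all(np.abs(dr) < 0.3)
            for dive in rec.dives:
                assert dive.dr_true == pytest.approx(float(t.trajectory(dive.day)))

    def test_haulout_keyed_to_final_buoyancy(self):
        params = dk.juvenile_defaults(n_individuals=20, trip_days_max=140.0, seed=2)
        pos_durs, neg_durs = [], []
        for rec in dk.iter_cohort(params):
            if not rec.haul_outs:
                assert rec.truth.tag_failure_day is not None
                continue
            dur = rec.haul_outs[0][1] - rec.haul_outs[0][0]
            final = float(rec.truth.trajectory(rec.truth.trip_end_day))
            (pos_durs if final > 0 else neg_durs).append(dur)
        assert np.mean(pos_durs) > np.mean(neg_durs)


class TestDriftObservations:
    def test_deterministic_and_matches_truth_band(self):
        params = dk.juvenile_defaults(n_individuals=3, trip_days_max=60.0, seed=21)
        a = dk.simulate_drift_observations(params)
        b = dk.simulate_drift_observations(params)
        for (ia, ta, da), (ib, tb, db) in zip(a, b):
            assert ia == ib
            assert da.equals(db)
            if len(da):
                resid = da["drift_rate"].to_numpy() - ta.trajectory(da["day"].to_numpy())
                assert np.abs(resid).max() < 5 * params.drift_noise_sd
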