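"""Drift filter rules, daily aggregation, and recovery against truth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import divekit as dk
from divekit.abstraction import DiveSegment, DiveSummary, abstract_cohort
from divekit.drift import daily_drift_series, drift_table, filter_drift_segments
from divekit.params import FilterThresholds

from oracles import drift_filter_oracle, random_summary


def make_dive(mid_rate=-0.12, mid_effort=1.2, mid_prca=0.0, mid_frac=0.55,
              duration=1000.0):
    """Three-segment dive whose interior segment has controllable properties."""
    mid = mid_frac * duration
    lead = (duration - mid) / 2
    edges = [0.0, lead, lead + mid, duration]
    depths = [0.0, 300.0, 300.0 - mid_rate * mid, 0.0]
    segs = []
    for i, role in enumerate(["descent", "bottom", "ascent"]):
        dur = edges[i + 1] - edges[i]
        rate = (depths[i] - depths[i + 1]) / dur
        eff = {0: 6.0, 1: mid_effort, 2: 6.0}[i]
        prca = mid_prca if i == 1 else 0.0
        segs.append(DiveSegment(i, edges[i], edges[i + 1], depths[i], depths[i + 1],
                                rate, eff * dur, eff, prca, role))
    return DiveSummary("d", "i", 0.0, max(depths), duration, 60.0, segs)


class TestFilterRules:
    def test_clean_interior_segment_passes(self):
        est = filter_drift_segments(make_dive())
        assert est is not None
        assert est.drift_rate == pytest.approx(-0.12)
        assert est.segment_duration_fraction == pytest.approx(0.55)

    @pytest.mark.parametrize("kwargs", [
        dict(mid_effort=4.5),                  # effort above 4 m/s^3
        dict(mid_prca=0.2),                    # PrCA detected
        dict(mid_rate=0.65),                   # rising too fast
        dict(mid_rate=-0.35),                  # sinking too fast
        dict(mid_rate=0.0),                    # null speed: resting on the floor
        dict(mid_frac=0.39),                   # under 40% of dive time
    ])
    def test_each_rule_rejects(self, kwargs):
        assert filter_drift_segments(make_dive(**kwargs)) is None

    def test_boundary_values_kept(self):
        # thresholds are exclusive: exactly 4 m/s^3 and 40% survive
        est = filter_drift_segments(make_dive(mid_effort=4.0, mid_frac=0.40))
        assert est is not None

    def test_optional_depth_gate(self):
        thr = FilterThresholds(min_drift_depth=65.0)
        shallow = make_dive()
        for s in shallow.segments:
            s.depth_start *= 0.1
            s.depth_end *= 0.1
        assert filter_drift_segments(shallow, thr) is None

    @pytest.mark.parametrize("order", [True, False])
    def test_oracle_equivalence_random_dives(self, order):
        """Keep/drop decisions match an independent transcription of the five
        rules, for both orderings of the speed and duration filters."""
        rng = np.random.Generator(np.random.PCG64(99))
        thr = FilterThresholds(speed_before_fraction=order)
        for _ in range(2000):
            dive = random_summary(rng)
            mine = filter_drift_segments(dive, thr)
            ref = drift_filter_oracle(dive)
            if ref is None:
                assert mine is None
            else:
                assert mine is not None
                assert mine.drift_rate == pytest.approx(ref, rel=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(st.integers(min_value=0, max_value=10 ** 6))
    def test_output_domain(self, seed):
        """Any returned drift rate lies in [-0.3, 0.6] \\ {0} with fraction >= 0.4."""
        rng = np.random.Generator(np.random.PCG64(seed))
        est = filter_drift_segments(random_summary(rng))
        if est is not None:
            assert -0.3 <= est.drift_rate <= 0.6
            assert abs(est.drift_rate) >= 1e-6
            assert est.segment_duration_fraction >= 0.40


class TestDailySeries:
    def test_identity_under_single_estimate_per_day(self):
        df = pd.DataFrame({"day": [0.1, 1.4, 2.9], "drift_rate": [-0.1, -0.15, -0.2]})
        series = daily_drift_series(df)
        assert list(series.daily.values) == [-0.1, -0.15, -0.2]

    def test_daily_median(self):
        df = pd.DataFrame({"day": [3.1, 3.5, 3.9], "drift_rate": [-0.1, -0.2, -0.3]})
        assert daily_drift_series(df).daily.loc[3] == pytest.approx(-0.2)

    def test_order_invariance(self, rng):
        df = pd.DataFrame({"day": rng.uniform(0, 30, 200),
                           "drift_rate": rng.uniform(-0.3, 0.3, 200)})
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = daily_drift_series(df)
        b = daily_drift_series(shuffled)
        pd.testing.assert_series_equal(a.daily, b.daily)
        pd.testing.assert_series_equal(a.smoothed, b.smoothed)

    def test_empty_input(self):
        series = daily_drift_series(pd.DataFrame(columns=["day", "drift_rate"]))
        assert len(series.daily) == 0 and len(series.smoothed) == 0


class TestRecovery:
    def test_smoothed_series_tracks_truth(self, small_juvenile_cohort):
        """RMSE against the generating drift rate stays below the observation
        noise, and the sign agrees on nearly all days with data."""
        _, records = small_juvenile_cohort
        for rec in records:
            _, _, summaries = abstract_cohort([rec])
            est = drift_table(summaries)
            series = daily_drift_series(est, rec.individual_id)
            sm = series.smoothed.dropna()
            if len(sm) < 10:
                continue
            truth = rec.truth.trajectory(np.asarray(sm.index, dtype=float))
            rmse = float(np.sqrt(np.mean((sm.to_numpy() - truth) ** 2)))
            assert rmse < 0.02
            sign_match = np.mean(np.sign(sm.to_numpy()) == np.sign(truth))
            assert sign_match >= 0.9

    def test_no_drift_dives_no_estimates(self):
        params = dk.juvenile_defaults(n_individuals=1, trip_days_max=5.0,
                                      drift_dive_prob=0.0, seed=4)
        _, _, summaries = abstract_cohort(dk.simulate_cohort(params))
        assert len(drift_table(summaries)) == 0
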