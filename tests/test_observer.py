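"""Synthetic-observer generative model: means, structure, determinism,
and the button-press adjustment micro-simulation."""

import numpy as np
import pandas as pd
import pytest

from chromadapt.observer import (
    CohortParams,
    ObserverParams,
    ScheduleConfig,
    expected_hue,
    simulate_adjustment_trace,
    simulate_cohort,
)
from conftest import noise_free_cohort


class TestExpectedHue:
    def test_first_on_glasses_is_baseline_plus_rapid(self):
        p = ObserverParams()
        got = expected_hue(p, day=1, session="AM", phase="on", minutes=0.0)
        assert got == pytest.approx(p.baseline0 + p.rapid_day1)

    def test_on_glasses_ramp_equals_gradual_slope(self):
        p = ObserverParams()
        rise = expected_hue(p, 2, "AM", "on", 60.0) - expected_hue(p, 2, "AM", "on", 0.0)
        assert rise == pytest.approx(p.gradual_slope)

    def test_post_removal_decays_to_baseline(self):
        p = ObserverParams()
        far = expected_hue(p, 3, "PM", "post", 1e6)
        assert far == pytest.approx(p.baseline0 + p.baseline_drift * 2)

    def test_rapid_adjustment_capped_at_full_compensation(self):
        p = ObserverParams(rapid_day1=-5.0, rapid_learn_rate=10.0)
        # by day 3 the uncapped rapid offset would be +15; settings must not
        # overshoot the no-glasses baseline
        assert expected_hue(p, 3, "AM", "on", 0.0) == pytest.approx(
            p.baseline0 + p.baseline_drift * 2
        )

    def test_followup_retains_fraction_of_learning(self):
        p = ObserverParams()
        r1 = p.rapid_day1
        r5 = p.rapid_day1 + 4 * p.rapid_learn_rate
        want = (p.baseline0 + 4 * p.baseline_drift) + r1 + p.retention * (r5 - r1)
        got = expected_hue(p, 0, "AM", "on", 0.0, followup=True, n_days=5)
        assert got == pytest.approx(want)

    def test_unknown_phase_rejected(self):
        with pytest.raises(ValueError, match="phase"):
            expected_hue(ObserverParams(), 1, "AM", "washout", 0.0)


class TestSimulateCohort:
    def test_deterministic_for_same_seed(self):
        a = simulate_cohort(CohortParams(n_observers=3, seed=11))
        b = simulate_cohort(CohortParams(n_observers=3, seed=11))
        pd.testing.assert_frame_equal(a, b)
        c = simulate_cohort(CohortParams(n_observers=3, seed=12))
        assert not a["hue_angle_deg"].equals(c["hue_angle_deg"])

    def test_structural_counts(self, default_records):
        df = default_records
        blocks = df.groupby(
            ["observer_id", "followup", "day", "session", "phase", "test_minute", "block"]
        ).size()
        # 11 observers x (5 days x 2 sessions + 1 follow-up session) x 10 tests x 5 blocks
        assert len(blocks) == 11 * (5 * 2 + 1) * 10 * 5
        assert (blocks >= 1).all()
        assert df["hue_angle_deg"].between(200, 360).all()

    def test_zero_noise_reproduces_expected_means_exactly(self, noise_free_records):
        df = noise_free_records
        p = ObserverParams(noise_sd=0.0, matches_per_block_mean=1.0)
        for (day, phase, minute, followup), grp in df.groupby(
            ["day", "phase", "test_minute", "followup"]
        ):
            want = expected_hue(p, day, "AM", phase, minute, followup=followup)
            np.testing.assert_allclose(grp["hue_angle_deg"], want)

    def test_ground_truth_attached(self, default_records):
        truth = default_records.attrs["truth"]
        assert len(truth) == 11
        assert {"rapid_learn_rate", "retention", "observer_id"} <= set(truth.columns)

    def test_followup_optional(self):
        sched = ScheduleConfig(include_followup=False)
        df = simulate_cohort(noise_free_cohort(2), sched)
        assert not df["followup"].any()


class TestTrendPrecisionScaling:
    def test_trend_se_follows_inverse_root_n(self):
        """The sampling SD of the recovered rapid-adjustment trend shrinks
        as 1/sqrt(n_observers): quadrupling the cohort roughly halves it."""
        import dataclasses

        from chromadapt.pipeline import baseline_correct, daily_trend, summarize_tests

        sched = ScheduleConfig(include_followup=False, blocks_per_test=2)

        def trend_sd(n_obs, seeds):
            means = ObserverParams(matches_per_block_mean=1.0)
            slopes = []
            for seed in seeds:
                cohort = CohortParams(n_observers=n_obs, means=means, seed=seed)
                rec = simulate_cohort(cohort, sched)
                corr = baseline_correct(summarize_tests(rec))
                first_on = corr[(corr["phase"] == "on") & (corr["test_minute"] == 0.0)]
                daily = (
                    first_on.groupby(["observer_id", "day"])["hue_value"]
                    .mean()
                    .reset_index()
                    .rename(columns={"hue_value": "value"})
                )
                slopes.append(daily_trend(daily).slope)
            return np.std(slopes, ddof=1)

        sd_small = trend_sd(11, range(40))
        sd_large = trend_sd(44, range(40, 80))
        ratio = sd_small / sd_large
        assert 1.4 < ratio < 2.9  # ideal 2.0, wide band for 40-replicate noise


class TestAdjustmentTrace:
    def test_already_on_target_accepts_without_presses(self):
        tr = simulate_adjustment_trace(300.0, seed=0, start=300.0, sigma_percept=0.0)
        assert tr.n_presses == 0
        assert tr.final == 300.0
        assert tr.accepted

    def test_monotone_approach_without_noise(self):
        tr = simulate_adjustment_trace(360.0, seed=0, start=250.0, sigma_percept=0.0)
        assert list(tr.trace) == sorted(tr.trace)
        assert tr.final == 360.0
        assert tr.elapsed_s <= 20.0

    def test_endpoint_pinning(self):
        # perceived target clipped to the green endpoint: never below 200
        tr = simulate_adjustment_trace(200.0, seed=1, start=230.0, sigma_percept=50.0)
        assert min(tr.trace) >= 200.0

    def test_no_endpoint_anchoring(self):
        """Once a trace touches an endpoint it stays pinned; no trace bounces
        off an endpoint and returns by a fixed number of steps."""
        for seed in range(60):
            tr = simulate_adjustment_trace(
                float(np.random.default_rng(seed).uniform(200, 360)), seed=seed
            )
            arr = np.array(tr.trace)
            for endpoint in (200.0, 360.0):
                hits = np.nonzero(arr == endpoint)[0]
                if hits.size:
                    assert np.all(arr[hits[0]:] == endpoint)

    def test_target_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            simulate_adjustment_trace(190.0, seed=0)

    def test_cap_limits_duration(self):
        tr = simulate_adjustment_trace(360.0, seed=2, start=200.0, sigma_percept=0.0)
        assert tr.elapsed_s <= 20.0
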