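"""Generator behaviour: determinism, planted-effect response, app rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import hfsense as h
from hfsense.actigraphy import SECONDS_PER_DAY, stream_to_counts
from hfsense.geolocation import haversine_km
from hfsense.synthetic import (
    effect_weights,
    generate_accel_stream,
    generate_call_log,
    generate_kccq_series,
    generate_location_trace,
    generate_motion_counts,
    inject_missingness,
)


def test_cohort_seeded_determinism():
    cfg = h.CohortConfig(n_participants=4, study_days=30, seed=5)
    a, b = h.generate_cohort(cfg), h.generate_cohort(cfg)
    pd.testing.assert_frame_equal(a.events, b.events)
    pd.testing.assert_frame_equal(a.calls, b.calls)
    pd.testing.assert_frame_equal(a.locations, b.locations)
    pd.testing.assert_frame_equal(a.kccq, b.kccq)
    for pid in a.participants:
        assert np.array_equal(a.motion_counts[pid].count, b.motion_counts[pid].count)
        assert np.array_equal(a.motion_counts[pid].present, b.motion_counts[pid].present)


def test_cohort_event_structure(small_cohort):
    ev = small_cohort.events
    assert set(ev["participant_id"]) <= set(small_cohort.participants)
    assert ev["day"].between(0, small_cohort.config.study_days - 1).all()
    assert set(ev["label"].unique()) <= {0, 1}


def test_decompensated_fraction_near_configured_rate():
    cfg = h.CohortConfig(n_participants=28, study_days=60, seed=9, motion_mode="counts")
    cohort = h.generate_cohort(cfg)
    frac = cohort.events["label"].mean()
    n = len(cohort.events)
    # binomial 3-sigma band around p = 48/110
    p = cfg.p_decompensated
    assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        h.CohortConfig(n_participants=0)
    with pytest.raises(ValueError):
        h.CohortConfig(p_decompensated=1.5)
    with pytest.raises(ValueError):
        h.EffectSizes(call_rate_factor=-0.5)


def test_neutral_effects_leave_call_counts_indistinguishable():
    """With neutral effect sizes, per-day call counts in 'effect' days match baseline."""
    w = np.zeros(400)
    w[100:300] = 1.0
    calls = generate_call_log(77, 400, 4.0, 120.0, 0.9, w, call_rate_factor=1.0, call_duration_factor=1.0)
    day = (calls["start"] // SECONDS_PER_DAY).astype(int)
    effect = day.between(100, 299)
    ks = stats.ks_2samp(
        calls.loc[effect, "duration_s"].to_numpy()[:500],
        calls.loc[~effect, "duration_s"].to_numpy()[:500],
    )
    assert ks.pvalue > 0.01


class TestAccelStream:
    def test_one_day_sample_count(self):
        s = generate_accel_stream(0, days=1, rate_hz=5.0)
        assert len(s) == 432_000

    def test_day_counts_exceed_night_counts(self):
        s = generate_accel_stream(1, days=2, rate_hz=5.0)
        counts = stream_to_counts(s)
        hour = (counts.epoch_start % SECONDS_PER_DAY) / 3600.0
        day = counts.count[(hour >= 10) & (hour < 20)]
        night = counts.count[(hour >= 0) & (hour < 6)]
        assert day.mean() > 5 * night.mean()

    def test_zero_motion_shift_suppresses_counts(self):
        w = np.array([0.0, 1.0])  # effect on day 2 only
        s = generate_accel_stream(2, days=2, rate_hz=5.0, day_weights=w, motion_shift=0.0)
        counts = stream_to_counts(s)
        hour = (counts.epoch_start % SECONDS_PER_DAY) / 3600.0
        daytime = (hour >= 10) & (hour < 20)
        d1 = counts.count[daytime & (counts.epoch_start < SECONDS_PER_DAY)]
        d2 = counts.count[daytime & (counts.epoch_start >= SECONDS_PER_DAY)]
        assert d2.mean() < 0.05 * d1.mean()

    def test_counts_mode_matches_raw_mode_statistics(self):
        raw = stream_to_counts(generate_accel_stream(3, days=2, rate_hz=5.0))
        direct = generate_motion_counts(3, days=2, rate_hz=5.0)
        hour = (raw.epoch_start % SECONDS_PER_DAY) / 3600.0
        daytime = (hour >= 9) & (hour < 21)
        ratio = direct.count[daytime].mean() / raw.count[daytime].mean()
        assert 0.8 < ratio < 1.25


class TestCallLog:
    def test_poisson_total_count(self):
        calls = generate_call_log(4, days=14, base_rate_per_day=4.0)
        assert abs(len(calls) - 56) <= 3 * np.sqrt(56)

    def test_rate_factor_halves_effect_interval(self):
        w = np.zeros(600)
        w[300:] = 1.0
        calls = generate_call_log(5, 600, 4.0, day_weights=w, call_rate_factor=0.5)
        day = (calls["start"] // SECONDS_PER_DAY).astype(int)
        n_base, n_eff = (day < 300).sum(), (day >= 300).sum()
        assert n_eff / n_base == pytest.approx(0.5, rel=0.15)

    def test_durations_positive(self):
        calls = generate_call_log(6, days=60)
        assert (calls["duration_s"] > 0).all()

    def test_duration_factor_raises_median(self):
        w = np.ones(300)
        base = generate_call_log(7, 300, 4.0, 120.0)
        longer = generate_call_log(7, 300, 4.0, 120.0, day_weights=w, call_duration_factor=1.6)
        assert np.median(longer["duration_s"]) / np.median(base["duration_s"]) == pytest.approx(1.6, rel=0.15)


class TestLocationTrace:
    def test_emitted_fixes_satisfy_app_rule(self):
        fixes = generate_location_trace(8, days=20, home_lat=41.0, home_lon=-74.0)
        t = fixes["t"].to_numpy()
        assert np.all(np.diff(t) >= 300.0)
        d = haversine_km(fixes["lat"][:-1].to_numpy(), fixes["lon"][:-1].to_numpy(),
                         fixes["lat"][1:].to_numpy(), fixes["lon"][1:].to_numpy())
        assert np.all(np.atleast_1d(d) >= 0.1)

    def test_stationary_trajectory_emits_at_most_one_fix(self):
        fixes = generate_location_trace(9, days=5, home_lat=41.0, home_lon=-74.0, excursions_per_day=0.0)
        assert len(fixes) <= 1

    def test_reduced_mobility_reduces_zone2_fixes(self):
        def zone2(factor):
            w = np.ones(60)
            fixes = generate_location_trace(10, 60, 41.0, -74.0, day_weights=w, mobility_radius_factor=factor)
            d = haversine_km(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(), 41.0, -74.0)
            return int(np.sum(np.atleast_1d(d) > 2.0))

        assert zone2(0.1) < zone2(1.0)


class TestKccqSeries:
    def test_weekly_cadence(self):
        resp = generate_kccq_series(11, days=28, baseline_domains=[70] * 4, p_skip=0.0)
        assert len(resp) == 4

    def test_planted_drop_moves_summary(self):
        w = np.ones(700)
        resp = generate_kccq_series(12, 700, [70.0] * 4, day_weights=w, kccq_drop=30.0, p_skip=0.0)
        summaries = resp[["phys", "symp", "qol", "social"]].mean(axis=1)
        assert summaries.mean() == pytest.approx(40.0, abs=2.0)

    def test_scores_clipped_to_range(self):
        resp = generate_kccq_series(13, 700, [15.0] * 4, kccq_drop=0.0)
        values = resp[["phys", "symp", "qol", "social"]].to_numpy()
        assert np.nanmin(values) >= 0.0 and np.nanmax(values) <= 100.0


class TestInjectMissingness:
    def _series(self, n):
        from hfsense.actigraphy import EpochCountSeries

        return EpochCountSeries("p", np.arange(n) * 30.0, np.ones(n), np.ones(n, bool))

    def test_zero_rate_identity(self):
        s = self._series(1000)
        out = inject_missingness(s, 0.0, seed=1)
        assert np.array_equal(out.present, s.present) and np.array_equal(out.count, s.count)

    def test_retained_fraction_near_target(self):
        s = self._series(30 * 2880)
        out = inject_missingness(s, 0.3, seed=2)
        retained = out.present.mean()
        assert 0.65 <= retained <= 0.75

    def test_deterministic(self):
        s = self._series(5000)
        a, b = inject_missingness(s, 0.2, seed=3), inject_missingness(s, 0.2, seed=3)
        assert np.array_equal(a.present, b.present)

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            inject_missingness(self._series(10), 1.0, seed=0)


def test_monotone_effect_response():
    """Stronger planted effects move the pre-event stream statistics monotonically."""
    w = np.ones(500)
    means = []
    for drop in (0.0, 15.0, 30.0):
        r = generate_kccq_series(20, 500, [75.0] * 4, day_weights=w, kccq_drop=drop, p_skip=0.0)
        means.append(r[["phys", "symp", "qol", "social"]].mean(axis=1).mean())
    assert means[0] > means[1] > means[2]

    counts = []
    for factor in (1.0, 0.7, 0.4):
        c = generate_call_log(21, 500, 4.0, day_weights=w, call_rate_factor=factor)
        counts.append(len(c))
    assert counts[0] > counts[1] > counts[2]


def test_effect_weights_shapes():
    w_step = effect_weights([20], [1], 30, 14, "step")
    w_lin = effect_weights([20], [1], 30, 14, "linear")
    assert w_step[6:20].tolist() == [1.0] * 14
    assert w_step[20] == 0.0 and w_step[5] == 0.0
    assert w_lin[19] == pytest.approx(1.0)
    assert w_lin[6] == pytest.approx(1 / 14)
    assert np.all(np.diff(w_lin[6:20]) > 0)
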