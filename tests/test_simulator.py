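"""Synthetic night generator: determinism, planted parameters, emission models."""

from dataclasses import replace

import numpy as np
import pytest

from nightwatch.simulator import (
    ConfigError,
    LoadcellConfig,
    ScenarioConfig,
    STATES,
    degrade_emfit,
    gen_loadcell,
    implied_event_matrix,
    simulate,
    simulate_night,
    single_phase,
    truncated_normal_moments,
    _matrix,
)
from nightwatch.signal_stats import rolling_window_stats, otsu_threshold
from nightwatch.transitions import TransitionModel


def record_signature(rec):
    return (
        rec.state_timeline,
        [(e.symbol, e.ts) for e in rec.ambient_events],
        [(e.symbol, e.ts) for e in rec.true_bed_events],
        [(e.symbol, e.ts) for e in rec.emfit_events],
        None if rec.adc is None else rec.adc.tobytes(),
    )


class TestDeterminism:
    def test_same_seed_and_night_give_identical_records(self):
        cfg = ScenarioConfig(seed=5, n_nights=1)
        a = simulate_night(cfg, 0)
        b = simulate_night(cfg, 0)
        assert record_signature(a) == record_signature(b)

    def test_different_nights_differ(self):
        cfg = ScenarioConfig(seed=5, n_nights=2)
        a, b = simulate(cfg, include_loadcell=False)
        assert record_signature(a) != record_signature(b)

    def test_emfit_parameters_do_not_touch_ground_truth(self):
        base = ScenarioConfig(seed=5, n_nights=1)
        a = simulate_night(base, 0)
        b = simulate_night(replace(base, emfit_miss_rate=0.0), 0)
        assert a.state_timeline == b.state_timeline
        assert [e.ts for e in a.true_bed_events] == [e.ts for e in b.true_bed_events]
        assert np.array_equal(a.adc, b.adc)


class TestTrajectory:
    def test_degenerate_chain_every_exit_goes_to_bathroom(self):
        m = _matrix({
            "Bed": {"Ba": 1.0}, "Ba": {"Bed": 1.0}, "K": {"Bed": 1.0},
            "H": {"Bed": 1.0}, "L": {"Bed": 1.0},
        })
        cfg = single_phase(ScenarioConfig(seed=6, n_nights=5, transition_matrix=m))
        for rec in simulate(cfg, include_loadcell=False):
            states = [s for s, _a, _b in rec.state_timeline]
            for prev, nxt in zip(states, states[1:]):
                assert (prev, nxt) in {("Bed", "Ba"), ("Ba", "Bed")}

    def test_invalid_matrix_rejected(self):
        bad = np.full((5, 5), 0.1)
        with pytest.raises(ConfigError):
            ScenarioConfig(transition_matrix=bad)

    def test_timeline_covers_night_contiguously(self):
        cfg = ScenarioConfig(seed=7, n_nights=1)
        rec = simulate_night(cfg, 0, include_loadcell=False)
        assert rec.state_timeline[0][1] == 0.0
        assert rec.state_timeline[-1][2] == pytest.approx(cfg.night_seconds)
        for (_s1, _a1, b1), (_s2, a2, _b2) in zip(rec.state_timeline,
                                                  rec.state_timeline[1:]):
            assert a2 == pytest.approx(b1)


class TestPlantedTransitionGap:
    def test_bed_to_bathroom_gap_recovers_truncated_normal_moments(self):
        """Planted Bout->Ba gap is a N(7, 7) min truncated at zero; the
        empirical moments over ~500 transitions must match the moments of
        that truncated distribution within 10%."""
        cfg = replace(single_phase(ScenarioConfig(seed=8, n_nights=160)),
                      pir_retrigger_s=None)
        gaps = []
        for rec in simulate(cfg, include_loadcell=False):
            events = rec.events_with_true_bed()
            for a, b in zip(events, events[1:]):
                if a.symbol == "Bout" and b.symbol == "Ba":
                    gaps.append((b.ts - a.ts).total_seconds())
        assert len(gaps) >= 400
        mu, sigma = truncated_normal_moments(7 * 60.0, 7 * 60.0)
        assert np.mean(gaps) == pytest.approx(mu, rel=0.10)
        assert np.std(gaps, ddof=1) == pytest.approx(sigma, rel=0.10)


class TestTransitionRecovery:
    def test_long_run_frequencies_converge_to_planted_matrix(self):
        cfg = replace(single_phase(ScenarioConfig(seed=9, n_nights=1200)),
                      pir_retrigger_s=None)
        model = TransitionModel()
        for rec in simulate(cfg, include_loadcell=False):
            model.observe_all(rec.events_with_true_bed())
        assert model.counts.sum() >= 2000
        p_hat = model.probability_matrix()
        p = implied_event_matrix(cfg)
        rows = ~np.isnan(p_hat).any(axis=1)
        assert rows.any()
        assert np.abs(p_hat[rows] - p[rows]).max() <= 0.05

    def test_implied_matrix_requires_single_phase(self):
        with pytest.raises(ConfigError):
            implied_event_matrix(ScenarioConfig())


class TestLoadcell:
    def test_sample_count_is_duration_times_rate(self):
        cfg = ScenarioConfig(seed=1, n_nights=1)
        rec = simulate_night(cfg, 0)
        assert rec.adc.size == int(8 * 3600 * 80)   # 2,304,000

    def test_zero_noise_config_gives_zero_sigma_off_bed(self):
        lc = LoadcellConfig(empty_sigma_kg=0.0, occupied_sigma_kg=0.0,
                            burst_rate_per_min=0.0)
        adc = gen_loadcell([(10.0, 20.0)], lc, np.random.default_rng(0), 30.0)
        _m, _mean, sigma = rolling_window_stats(adc / lc.adc_ratio)
        # windows fully outside the bed interval are exactly flat
        assert sigma[:int(10 * 80 / 40)].max() == 0.0

    def test_default_sigma_histogram_is_separable_by_otsu(self):
        cfg = ScenarioConfig(seed=2, n_nights=1)
        rec = simulate_night(cfg, 0)
        _m, _mean, sigma = rolling_window_stats(rec.weights)
        thr = otsu_threshold(np.minimum(sigma, np.quantile(sigma, 0.95)))
        ends = (np.arange(1, sigma.size + 1) * 40) / 80.0
        truth = np.zeros(sigma.size, dtype=bool)
        for a, b in rec.bed_intervals:
            truth |= (ends > a) & (ends <= b)
        assert ((sigma >= thr) != truth).mean() <= 0.02

    def test_adc_round_trips_to_weight_scale(self):
        lc = LoadcellConfig(empty_sigma_kg=0.0, occupied_sigma_kg=0.0,
                            burst_rate_per_min=0.0)
        adc = gen_loadcell([], lc, np.random.default_rng(0), 1.0)
        np.testing.assert_allclose(adc / lc.adc_ratio, lc.empty_mean_kg, atol=1e-4)


class TestEmfitDegradation:
    def make_bouts(self, make_event, n):
        return [make_event("Bout", 60.0 * i) for i in range(n)]

    def test_zero_miss_rate_keeps_stream(self, make_event):
        bouts = self.make_bouts(make_event, 50)
        out = degrade_emfit(bouts, miss_rate=0.0, rng=0)
        assert [e.ts for e in out] == [e.ts for e in bouts]
        assert all(e.source == "emfit" for e in out)

    def test_full_miss_rate_drops_every_exit(self, make_event):
        assert degrade_emfit(self.make_bouts(make_event, 50), 1.0, rng=0) == []

    def test_entrances_pass_through(self, make_event):
        events = [make_event("Bin", 0.0), make_event("Bout", 100.0)]
        out = degrade_emfit(events, miss_rate=1.0, rng=0)
        assert [e.symbol for e in out] == ["Bin"]

    def test_retention_within_binomial_bounds(self, make_event):
        bouts = self.make_bouts(make_event, 1000)
        kept = len(degrade_emfit(bouts, miss_rate=0.6, rng=3))
        sigma3 = 3 * np.sqrt(1000 * 0.6 * 0.4)   # ~46
        assert abs(kept - 400) <= sigma3

    def test_invalid_miss_rate_rejected(self, make_event):
        with pytest.raises(ValueError):
            degrade_emfit([], miss_rate=1.5)


class TestEventConsistency:
    def test_room_events_fire_inside_their_room_interval(self):
        cfg = ScenarioConfig(seed=10, n_nights=2)
        for rec in simulate(cfg, include_loadcell=False):
            room_iv = {}
            for s, a, b in rec.state_timeline:
                if s != "Bed":
                    room_iv.setdefault(s, []).append((a, b))
            for e in rec.ambient_events:
                if e.symbol in ("Ba", "K", "H", "L"):
                    t = (e.ts - rec.night_start).total_seconds()
                    assert any(a <= t < b for a, b in room_iv[e.symbol])

    def test_bed_events_align_with_timeline(self):
        cfg = ScenarioConfig(seed=10, n_nights=1)
        rec = simulate_night(cfg, 0, include_loadcell=False)
        expected = []
        for s, a, b in rec.state_timeline:
            if s == "Bed":
                if a > 0:
                    expected.append(("Bin", a))
                if b < cfg.night_seconds:
                    expected.append(("Bout", b))
        got = [(e.symbol, (e.ts - rec.night_start).total_seconds())
               for e in rec.true_bed_events]
        assert [(s, pytest.approx(t, abs=1e-6)) for s, t in expected] == got
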