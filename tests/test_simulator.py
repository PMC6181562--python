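import logging

import numpy as np
import pytest
from scipy import stats

from strobe import (
    CalciumConfig,
    Channel,
    DetectorParams,
    SessionConfig,
    SipModel,
    derive_fly_seed,
    detect,
    simulate_calcium_trace,
    simulate_cohort,
    simulate_session,
    summarize_cohort,
)


def planted_on(planted, channel):
    return [p for p in planted if p.channel == channel]


class TestSimulateSession:
    def test_deterministic_given_seed(self, short_session):
        (a1, a2), pa = simulate_session(short_session)
        (b1, b2), pb = simulate_session(short_session)
        np.testing.assert_array_equal(a1.values, b1.values)
        np.testing.assert_array_equal(a2.values, b2.values)
        assert pa == pb

    def test_different_seeds_differ(self, short_session):
        from dataclasses import replace

        (a1, _), _ = simulate_session(short_session)
        (b1, _), _ = simulate_session(replace(short_session, seed=99))
        assert not np.array_equal(a1.values, b1.values)

    def test_rate_zero_plants_nothing(self):
        cfg = SessionConfig(
            duration=60, sip_food1=SipModel(rate=0.0), sip_food2=SipModel(rate=0.0),
            seed=4,
        )
        (tr1, tr2), planted = simulate_session(cfg)
        assert planted == []
        # trace is baseline + drift + noise, nowhere near a sip amplitude
        for tr in (tr1, tr2):
            assert tr.values.max() - tr.values.min() < 500

    def test_default_session_is_an_hour_at_100hz(self):
        cfg = SessionConfig(seed=0)
        assert cfg.duration == 3600.0
        assert cfg.n_samples == 360_000

    def test_planted_count_mean_matches_rate_times_duration(self):
        # 200 seeds x 300 s at 0.05 sips/s: mean count within 3 SE of 15
        rate, duration, n_seeds = 0.05, 300.0, 200
        counts = []
        for seed in range(n_seeds):
            cfg = SessionConfig(
                duration=duration, noise_sd=0.0, drift_amplitude=0.0,
                sip_food1=SipModel(rate=rate), sip_food2=SipModel(rate=0.0),
                seed=seed,
            )
            _, planted = simulate_session(cfg)
            counts.append(len(planted_on(planted, Channel.FOOD1)))
        counts = np.array(counts)
        expected = rate * duration
        se = counts.std(ddof=1) / np.sqrt(n_seeds)
        assert abs(counts.mean() - expected) < 3 * se

    def test_planted_counts_consistent_with_poisson(self):
        # burstiness 1 makes gaps exponential, so counts are Poisson;
        # chi-square goodness of fit must not reject at alpha = 0.01
        rate, duration, n_seeds = 0.05, 300.0, 200
        counts = []
        for seed in range(n_seeds):
            cfg = SessionConfig(
                duration=duration, noise_sd=0.0, drift_amplitude=0.0,
                sip_food1=SipModel(rate=rate), sip_food2=SipModel(rate=0.0),
                seed=seed,
            )
            _, planted = simulate_session(cfg)
            counts.append(len(planted_on(planted, Channel.FOOD1)))
        counts = np.array(counts)
        mu = rate * duration
        edges = [-0.5, 9.5, 12.5, 15.5, 18.5, 21.5, np.inf]
        observed = np.histogram(counts, bins=edges)[0]
        cdf = stats.poisson(mu).cdf
        probs = np.diff([cdf(e) for e in edges])
        chi2, p = stats.chisquare(observed, probs * n_seeds)
        assert p > 0.01

    def test_planted_events_disjoint_and_sorted_per_channel(self, short_session):
        _, planted = simulate_session(short_session)
        for channel in Channel:
            evs = planted_on(planted, channel)
            for a, b in zip(evs, evs[1:]):
                assert a.offset_index < b.onset_index

    def test_overlapping_pulses_are_merged_with_warning(self, caplog):
        cfg = SessionConfig(
            duration=60, sip_food1=SipModel(rate=5.0), sip_food2=SipModel(rate=0.0),
            seed=1,
        )
        with caplog.at_level(logging.WARNING, logger="strobe.simulator"):
            _, planted = simulate_session(cfg)
        assert any("merged" in r.message for r in caplog.records)
        evs = planted_on(planted, Channel.FOOD1)
        for a, b in zip(evs, evs[1:]):
            assert a.offset_index < b.onset_index


class TestGroundTruthRecovery:
    def test_detector_recovers_planted_sips(self):
        # amplitude 500 >= threshold + 5 x noise SD, pulses >= 3 samples:
        # every planted event should be matched by interval overlap
        hits = total = false_pos = 0
        for seed in range(5):
            cfg = SessionConfig(duration=600, seed=seed)
            (tr1, tr2), planted = simulate_session(cfg)
            for tr in (tr1, tr2):
                _, events = detect(tr, DetectorParams())
                mine = planted_on(planted, tr.channel)
                total += len(mine)
                for p in mine:
                    hits += any(
                        e.onset_index <= p.offset_index and p.onset_index <= e.offset_index
                        for e in events
                    )
                false_pos += sum(
                    not any(p.overlaps(e.onset_index, e.offset_index) for p in mine)
                    for e in events
                )
        assert total > 0
        assert hits / total >= 0.99
        assert false_pos == 0


class TestSimulateCohort:
    def test_single_fly_reproduces_session_for_derived_seed(self, short_session):
        from dataclasses import replace

        model = SipModel(rate=0.1)
        (fly,) = simulate_cohort(1, model, model, short_session, seed=21)
        cfg = replace(
            short_session, sip_food1=model, sip_food2=model,
            seed=derive_fly_seed(21, 0),
        )
        _, planted = simulate_session(cfg)
        assert fly.ground_truth == tuple(planted)

    def test_symmetric_rates_give_zero_mean_preference(self):
        model = SipModel(rate=0.1)
        sessions = simulate_cohort(
            50, model, model, SessionConfig(duration=600), seed=5
        )
        s = summarize_cohort(sessions)
        assert abs(s.mean_preference) < 3 * s.sem_preference

    def test_asymmetric_rates_recover_expected_preference(self):
        # lambda1 = 0.14, lambda2 = 0.06 over 600 s: expected PI
        # (l1 - l2)/(l1 + l2) = 0.4 for large counts
        sessions = simulate_cohort(
            50, SipModel(rate=0.14), SipModel(rate=0.06),
            SessionConfig(duration=600), seed=6,
        )
        s = summarize_cohort(sessions)
        assert abs(s.mean_preference - 0.4) < 3 * s.sem_preference


class TestSimulateCalcium:
    def test_flat_when_response_and_noise_are_zero(self):
        trace = simulate_calcium_trace(CalciumConfig(true_dff=0.0, noise_sd=0.0))
        np.testing.assert_allclose(trace.values, 100.0)

    def test_timeline_length(self):
        cfg = CalciumConfig(frame_period=0.1)
        trace = simulate_calcium_trace(cfg)
        assert len(trace) == 150  # (5 + 1 + 9) s at 10 Hz
        assert trace.stim_onset == pytest.approx(5.0)

    def test_deterministic_given_seed(self):
        cfg = CalciumConfig(noise_sd=2.0, seed=3)
        a = simulate_calcium_trace(cfg)
        b = simulate_calcium_trace(cfg)
        np.testing.assert_array_equal(a.values, b.values)

    def test_response_starts_at_stimulus_onset(self):
        trace = simulate_calcium_trace(CalciumConfig(true_dff=0.5, noise_sd=0.0))
        onset = trace.stim_onset_index
        np.testing.assert_allclose(trace.values[:onset], 100.0)
        assert trace.values[onset:].max() > 100.0
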