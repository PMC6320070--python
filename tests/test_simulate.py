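"""Generator properties: state tiling, refractory, thinning calibration."""
import numpy as np
import pytest

import reafference as rf
from reafference.simulate import (
    LFPParams,
    NeuronParams,
    integrated_rate,
    rate_function,
    simulate_coupled_pair,
    simulate_emg,
    simulate_event_train,
    simulate_laminar_lfp,
    simulate_spike_train,
    simulate_states,
)


class TestStates:
    def test_tiles_session_and_alternates(self):
        states = simulate_states(1800.0, 60.0, 30.0, seed=0)
        iv = states.intervals
        assert iv[0][0] == 0.0 and iv[-1][1] == 1800.0
        for (s0, e0, st0), (s1, e1, st1) in zip(iv, iv[1:]):
            assert e0 == s1 and st0 != st1

    def test_active_sleep_fraction_matches_bout_means(self):
        # mean bouts 60 s AS / 30 s wake -> expected AS fraction 2/3
        fracs = [
            simulate_states(1800.0, 60.0, 30.0, seed=s).total("active_sleep") / 1800.0
            for s in range(100)
        ]
        assert abs(np.mean(fracs) - 2.0 / 3.0) < 0.02

    def test_zero_duration_empty(self):
        assert simulate_states(0.0, 60.0, 30.0, seed=0).intervals == []

    def test_deterministic(self):
        a = simulate_states(600.0, 60.0, 30.0, seed=42).intervals
        b = simulate_states(600.0, 60.0, 30.0, seed=42).intervals
        assert a == b

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            simulate_states(-1.0, 60.0, 30.0)
        with pytest.raises(ValueError):
            simulate_states(100.0, 3.0, 30.0)  # mean below the 5 s floor


class TestEventTrain:
    def test_count_matches_dead_time_expectation(self):
        # renewal gaps = refractory + Exp(1/rate): E[N] ~ T / (refractory + 1/rate);
        # rate 0.272 over 1200 s -> ~302 events, the young-age session scale
        iv = np.array([[0.0, 1200.0]])
        counts = [
            len(simulate_event_train(0.272, iv, 0.3, seed=s)) for s in range(30)
        ]
        expected = 1200.0 / (0.3 + 1.0 / 0.272)
        assert abs(np.mean(counts) - expected) < 3 * np.sqrt(expected) / np.sqrt(30)
        assert 302 == pytest.approx(expected, rel=0.02)

    def test_zero_rate_empty(self):
        assert len(simulate_event_train(0.0, [[0, 100]], 0.3, seed=0)) == 0

    def test_refractory_invariant_and_interval_restriction(self):
        iv = np.array([[10.0, 50.0], [80.0, 200.0]])
        train = simulate_event_train(1.5, iv, 0.3, seed=3)
        assert train.min_gap() >= 0.3
        inside = ((train.times >= 10) & (train.times < 50)) | (
            (train.times >= 80) & (train.times < 200)
        )
        assert inside.all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_event_train(-1.0, [[0, 10]], 0.3)


class TestSpikeTrain:
    def test_count_matches_integrated_rate(self):
        events = simulate_event_train(0.3, [[0, 600.0]], 0.3, seed=1).times
        p = NeuronParams(2.12, 3.86, 0.194, 0.158, response_type="twitch")
        train = simulate_spike_train(p, 600.0, twitch_times=events, seed=2)
        mu = integrated_rate(p, 600.0, twitch_times=events)
        assert abs(len(train) - mu) <= 4 * np.sqrt(mu)

    def test_no_response_is_homogeneous_baseline(self):
        p = NeuronParams(3.0, 0.0, 0.1, 0.05, response_type="none")
        train = simulate_spike_train(p, 1000.0, seed=4)
        assert len(train) / 1000.0 == pytest.approx(3.0, abs=4 * np.sqrt(3.0 / 1000.0) * 3)

    def test_psth_peak_near_t_max(self):
        # P8 twitch medians: BL 2.12, R_max 3.86, t_max 0.194, HWHH 0.186
        c = 0.186 / np.sqrt(2 * np.log(2))
        p = NeuronParams(2.12, 3.86, 0.194, c, response_type="twitch")
        events = simulate_event_train(0.3, [[0, 1200.0]], 0.3, seed=5)
        train = simulate_spike_train(p, 1200.0, twitch_times=events.times, seed=6)
        psth = rf.build_psth(train, events)
        peak_t = psth.bin_centers[np.argmax(np.convolve(psth.rates, np.ones(5) / 5, "same"))]
        assert abs(peak_t - 0.194) < 0.1

    def test_deterministic(self):
        p = NeuronParams(2.0, 3.0, 0.1, 0.05)
        a = simulate_spike_train(p, 100.0, twitch_times=[10, 20], seed=9)
        b = simulate_spike_train(p, 100.0, twitch_times=[10, 20], seed=9)
        assert np.array_equal(a.times, b.times)

    def test_rate_function_kernel_shapes(self):
        p_wake = NeuronParams(1.0, 10.0, 0.1, 0.05, 0.25, response_type="wake")
        t = np.array([0.05, 0.1, 0.35])  # rise, peak, decay of one event at 0
        lam = rate_function(t, p_wake, wake_times=[0.0])
        assert lam[1] == pytest.approx(11.0)
        assert lam[2] == pytest.approx(1.0 + 10.0 * np.exp(-0.25 / 0.25), rel=1e-9)
        assert lam[0] < lam[1]


class TestEMG:
    def test_quiet_sleep_envelope_at_baseline(self):
        states = rf.StateIntervals([(0.0, 60.0, "active_sleep")])
        emg = simulate_emg(states, 60.0, rf.EMGParams(), seed=0)
        env = rf.rectify_smooth(emg, 0.01)
        assert np.median(env.values) == pytest.approx(1.0, rel=0.15)
        assert env.values.max() < 2.0

    def test_single_twitch_burst_exceeds_threshold(self):
        states = rf.StateIntervals([(0.0, 60.0, "active_sleep")])
        emg = simulate_emg(states, 60.0, rf.EMGParams(), twitch_times=[10.0], seed=1)
        env = rf.rectify_smooth(emg, 0.001)
        sel = (env.times >= 10.0) & (env.times <= 10.1)
        baseline = np.median(env.values)
        assert env.values[sel].max() >= 3.0 * baseline

    def test_wake_movement_burst_sustained(self):
        states = rf.StateIntervals([(0.0, 60.0, "wake")])
        p = rf.EMGParams()
        emg = simulate_emg(states, 60.0, p, wake_move_times=[20.0], seed=2)
        env = rf.rectify_smooth(emg, 0.01)
        thr = 5.0 * p.baseline * p.wake_tone_mult
        above = env.values > thr
        runs = np.diff(np.flatnonzero(np.diff(above.astype(int)) != 0))
        assert above.sum() / env.fs >= 0.3  # supra-threshold for >= 300 ms


class TestCoupledPairAndLFP:
    def test_zero_coupling_gives_flat_corrected(self):
        events = simulate_event_train(0.3, [[0, 600]], 0.3, seed=7).times
        p = NeuronParams(3.0, 10.0, 0.05, 0.03)
        a, b = simulate_coupled_pair(p, 600.0, twitch_times=events,
                                     coupling_prob=0.0, seed=8)
        cs = rf.pair_correlogram(b, a, events)
        assert cs.significant.mean() <= 0.03  # ~nominal 1% at p=0.01

    def test_coupling_lag_recovered(self):
        events = simulate_event_train(0.3, [[0, 900]], 0.3, seed=9).times
        p = NeuronParams(3.0, 10.0, 0.05, 0.03)
        a, b = simulate_coupled_pair(p, 900.0, twitch_times=events,
                                     lag=0.015, coupling_prob=0.3, seed=10)
        cs = rf.pair_correlogram(b, a, events)
        assert rf.peak_lag(cs) == pytest.approx(0.015, abs=0.002)

    def test_pair_deterministic(self):
        p = NeuronParams(3.0, 5.0, 0.05, 0.03)
        a1, b1 = simulate_coupled_pair(p, 200.0, twitch_times=[50.0], seed=3)
        a2, b2 = simulate_coupled_pair(p, 200.0, twitch_times=[50.0], seed=3)
        assert np.array_equal(a1.times, a2.times) and np.array_equal(b1.times, b2.times)

    def test_noiseless_dipole_sink_site_exact(self):
        lfp = simulate_laminar_lfp(LFPParams(sink_depth=800.0), [5.0], 10.0, seed=0)
        evoked = rf.evoked_potential(lfp, [5.0])
        cmap = rf.compute_csd(evoked)
        site_min = np.unravel_index(np.argmin(cmap.csd), cmap.csd.shape)[0]
        assert cmap.site_depths[site_min] == 800.0

    def test_zero_amplitude_flat(self):
        lfp = simulate_laminar_lfp(
            LFPParams(sink_depth=800.0, amplitude=0.0), [5.0], 10.0, seed=0
        )
        assert np.allclose(lfp.series, 0.0)

    def test_sink_outside_probe_rejected(self):
        with pytest.raises(ValueError):
            simulate_laminar_lfp(LFPParams(sink_depth=5000.0), [5.0], 10.0)


class TestSessionBundle:
    def test_events_respect_states_and_refractory(self, session_bundle):
        b = session_bundle
        as_iv = b.states.of_state("active_sleep")
        wake_iv = b.states.of_state("wake")
        tw = b.event_trains["twitch_forelimb"]
        assert tw.min_gap() >= 0.3
        in_as = np.zeros(len(tw), dtype=bool)
        for s, e in as_iv:
            in_as |= (tw.times >= s) & (tw.times < e)
        assert in_as.all()
        mv = b.event_trains["wake_movement_scored_forelimb"]
        in_wake = np.zeros(len(mv), dtype=bool)
        for s, e in wake_iv:
            in_wake |= (mv.times >= s) & (mv.times < e)
        assert in_wake.all()

    def test_bundle_bit_identical_across_runs(self):
        cfg = rf.SimConfig(session_duration=120.0, seed=77)
        b1, b2 = rf.simulate_session(cfg), rf.simulate_session(cfg)
        assert b1.states.intervals == b2.states.intervals
        for k in b1.event_trains:
            assert np.array_equal(b1.event_trains[k].times, b2.event_trains[k].times)
        for s1, s2 in zip(b1.spikes, b2.spikes):
            assert np.array_equal(s1.times, s2.times)
        for m in b1.emg:
            assert np.array_equal(b1.emg[m].samples, b2.emg[m].samples)
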