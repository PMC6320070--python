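"""Perievent histograms, model fits, adjusted r2, classification."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import reafference as rf
from reafference.psth import gauss_exp_model, gaussian_model

SQ2LN2 = np.sqrt(2 * np.log(2))


def psth_from_rates(rates):
    edges = -1.0 + 0.01 * np.arange(201)
    return rf.Psth(edges, rates, n_events=200)


class TestBuildPsth:
    def test_hand_counted_single_bin(self):
        events = np.arange(10.0, 110.0, 10.0)  # 10 events
        # one spike 55 ms after each event -> bin [0.05, 0.06) = 100 sps
        spikes = rf.SpikeTrain("u0", np.sort(events + 0.055), span=(0, 200))
        psth = rf.build_psth(spikes, events)
        assert psth.rates.size == 200  # 2000 ms window / 10 ms bins
        i = int(np.argmax(psth.rates))
        assert psth.bin_edges[i] <= 0.055 < psth.bin_edges[i + 1]
        assert psth.rates[i] == pytest.approx(100.0)
        assert psth.rates.sum() == pytest.approx(100.0)

    def test_no_spikes_all_zero(self):
        spikes = rf.SpikeTrain("u0", np.empty(0))
        psth = rf.build_psth(spikes, [1.0, 2.0])
        assert np.all(psth.rates == 0)

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError, match="no trigger"):
            rf.build_psth(rf.SpikeTrain("u0", [1.0]), [])

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_mass_conservation(self, seed):
        # sum(rates) * bin * n_events == total in-window spike count
        rng = np.random.default_rng(seed)
        spikes = rf.SpikeTrain("u0", np.sort(rng.uniform(0, 100, size=rng.integers(0, 400))))
        events = np.sort(rng.uniform(2, 98, size=rng.integers(1, 20)))
        psth = rf.build_psth(spikes, events)
        total = sum(
            np.sum((spikes.times >= te - 1.0) & (spikes.times < te + 1.0))
            for te in events
        )
        assert psth.rates.sum() * 0.010 * len(events) == pytest.approx(total)


class TestAdjustedR2:
    def test_perfect_prediction(self):
        r2, flag = rf.adjusted_r2([1, 2, 3, 4], [1, 2, 3, 4], p=2)
        assert r2 == 1.0 and not flag

    def test_mean_prediction_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        r2, _ = rf.adjusted_r2(obs, np.full(4, obs.mean()), p=1)
        assert r2 == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # SSE=1, SST=5, n=4, p=2: 1 - (3/2)(1/5) = 0.70
        r2, _ = rf.adjusted_r2([1, 2, 3, 4], [1, 2, 2, 4], p=2)
        assert r2 == pytest.approx(0.70)

    def test_degenerate_and_invalid(self):
        r2, flag = rf.adjusted_r2([2.0, 2.0, 2.0], [2.0, 2.0, 2.0], p=1)
        assert r2 == 0.0 and flag
        with pytest.raises(ValueError):
            rf.adjusted_r2([1.0, 2.0], [1.0, 2.0], p=2)


class TestFits:
    def test_gaussian_noiseless_recovery(self):
        edges = -1.0 + 0.01 * np.arange(201)
        t = 0.5 * (edges[:-1] + edges[1:])
        rates = gaussian_model(t, 2.0, 10.0, 0.10, 0.05)
        fit = rf.fit_gaussian(psth_from_rates(rates))
        assert fit.SSE < 1e-12 and fit.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert (fit.BL, fit.R_max, fit.t_max, fit.c) == pytest.approx(
            (2.0, 10.0, 0.10, 0.05), abs=1e-6
        )

    def test_gauss_exp_noiseless_recovery(self):
        edges = -1.0 + 0.01 * np.arange(201)
        t = 0.5 * (edges[:-1] + edges[1:])
        rates = gauss_exp_model(t, 1.0, 8.0, 0.05, 0.04, 5.0)
        fit = rf.fit_gauss_exp(psth_from_rates(rates))
        assert fit.SSE < 1e-12 and fit.r2_adj == pytest.approx(1.0, abs=1e-9)
        assert (fit.BL, fit.R_max, fit.t_max, fit.c, fit.lam) == pytest.approx(
            (1.0, 8.0, 0.05, 0.04, 5.0), abs=1e-5
        )
        assert fit.p == 5

    def test_all_zero_psth_degenerate(self):
        fit = rf.fit_gaussian(psth_from_rates(np.zeros(200)))
        assert fit.degenerate and fit.r2_adj == 0.0 and fit.R_max == 0.0

    def test_model_continuous_at_peak(self):
        # both branches equal BL + R_max at t_max
        v = gauss_exp_model(np.array([0.1]), 1.0, 8.0, 0.1, 0.04, 5.0)
        assert v[0] == pytest.approx(9.0)

    def test_monte_carlo_recovery_p8_twitch_medians(self):
        # BL 2.12, R_max 3.86, t_max 0.194 s with 300 events: parameters
        # recovered within +-20% (median over seeds)
        from reafference.simulate import NeuronParams, simulate_event_train, simulate_spike_train

        c = 0.186 / SQ2LN2
        p = NeuronParams(2.12, 3.86, 0.194, c, response_type="twitch")
        errs = []
        for seed in range(10):
            ev = simulate_event_train(0.272, [[0, 1200.0]], 0.3, seed=seed)
            train = simulate_spike_train(p, 1200.0, twitch_times=ev.times, seed=seed + 500)
            fit = rf.fit_gaussian(rf.build_psth(train, ev))
            errs.append(
                (
                    abs(fit.BL / 2.12 - 1),
                    abs(fit.R_max / 3.86 - 1),
                    abs(fit.t_max - 0.194),
                )
            )
        med = np.median(np.asarray(errs), axis=0)
        assert med[0] <= 0.2 and med[1] <= 0.2 and med[2] <= 0.02


class TestWidths:
    def test_hwhh_identity(self):
        fit = rf.ResponseFit("gaussian", 0, 1, 0, 1.0, None, 0, 1, 200, 4, 1.0)
        hwhh, t_half = rf.derive_widths(fit)
        assert hwhh == pytest.approx(1.17741, abs=1e-5)
        assert t_half is None

    def test_scaling_and_half_life(self):
        fit = rf.ResponseFit("gauss_exp", 0, 1, 0, 0.05, np.log(2), 0, 1, 200, 5, 1.0)
        hwhh, t_half = rf.derive_widths(fit)
        assert hwhh == pytest.approx(0.05887, abs=1e-5)
        assert t_half == pytest.approx(1.0)

    def test_fast_decay_limit(self):
        fit = rf.ResponseFit("gauss_exp", 0, 1, 0, 0.05, 1e9, 0, 1, 200, 5, 1.0)
        assert rf.derive_widths(fit)[1] < 1e-8


def _fit(r2):
    return rf.ResponseFit("gaussian", 1, 1, 0.1, 0.05, None, 0, 1, 200, 4, r2)


class TestClassification:
    @pytest.mark.parametrize(
        "r2t,r2w,label",
        [
            (0.50, 0.20, "twitch"),
            (0.35, 0.35, "unresponsive"),  # strict inequality at the threshold
            (0.40, 0.80, "twitch_and_wake"),
            (0.10, 0.36, "wake"),
        ],
    )
    def test_four_way_partition(self, r2t, r2w, label):
        assert rf.classify_neuron(_fit(r2t), _fit(r2w)).label == label

    def test_missing_fit_counts_as_zero(self):
        assert rf.classify_neuron(None, _fit(0.5)).label == "wake"


class TestPopulationSummary:
    def test_p12_m1_worked_example(self):
        # counts: unresponsive 102, wake 48, twitch 3, both 12, N=165
        s = rf.summary_from_counts(102, 48, 3, 12)
        assert s.N_total == 165
        assert s.P_R_total == pytest.approx(100 * 63 / 165, abs=1e-9)  # 38.2%
        assert s.pct_twitch_inclusive == pytest.approx(100 * 15 / 63)  # ~23.8 -> "24%"
        assert round(s.pct_twitch_inclusive) == 24

    def test_p8_all_responsive_twitch(self):
        s = rf.summary_from_counts(84, 0, 64, 12)
        assert s.pct_twitch_inclusive == pytest.approx(100.0)

    def test_all_unresponsive(self):
        s = rf.summary_from_counts(10, 0, 0, 0)
        assert s.P_R_total == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rf.population_summary([])


class TestThresholdSensitivity:
    def test_counts_invariant_when_all_strongly_responsive(self):
        fits = [(_fit(0.6), _fit(0.7))] * 5
        rows = rf.threshold_sensitivity(fits)
        assert all(r["twitch_and_wake"] == 5 for r in rows)

    def test_grid_contains_anchor_threshold(self):
        rows = rf.threshold_sensitivity([(_fit(0.5), _fit(0.1))])
        assert 0.35 in [r["threshold"] for r in rows]


class TestDepthProfile:
    def _trains(self, depths, responsive, seed=0):
        from reafference.simulate import NeuronParams, simulate_event_train, simulate_spike_train

        ev = simulate_event_train(0.3, [[0, 600.0]], 0.3, seed=seed)
        trains = []
        for i, (d, resp) in enumerate(zip(depths, responsive)):
            p = NeuronParams(3.0, 12.0 if resp else 0.0, 0.1, 0.05,
                             response_type="twitch" if resp else "none")
            tr = simulate_spike_train(p, 600.0, twitch_times=ev.times,
                                      seed=seed + i + 1, unit_id=f"u{i}")
            trains.append(rf.SpikeTrain(tr.unit_id, tr.times, "M1", tr.span, depth=d))
        return trains, ev

    def test_deep_responders_dominate_profile(self):
        depths = [100.0, 300.0, 800.0, 1000.0]
        trains, ev = self._trains(depths, [False, False, True, True])
        profile, flagged = rf.depth_response_profile(trains, ev)
        values = dict(profile)
        assert max(values, key=values.get) in (800.0, 1000.0)
        assert values[800.0] > 2 * max(values[100.0], values[300.0])

    def test_silent_site_flagged(self):
        trains, ev = self._trains([100.0, 200.0], [True, True])
        silent = rf.SpikeTrain("dead", np.empty(0), "M1", (0, 600), depth=300.0)
        profile, flagged = rf.depth_response_profile(trains + [silent], ev)
        assert flagged == ["dead"]
        assert all(d != 300.0 for d, _ in profile)
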