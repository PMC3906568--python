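"""Electrophysiology analyses against closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurorig.ephys import (MapSite, charge_transfer, classify_map_sites,
                            detect_events, detect_spikes, export_map_csv,
                            export_map_sqlite, frame_times_from_exposure,
                            iv_metrics, membrane_properties)
from neurorig.signals import Trace
from neurorig.simdevices import CellModel, sim_clamp_response, sim_lif_response

RATE = 100e3


def make_pulse(amp=-10e-3, total=0.2, start=0.05, length=0.1, units="V"):
    cmd = np.zeros(int(total * RATE))
    cmd[int(start * RATE):int((start + length) * RATE)] = amp
    return Trace(cmd, RATE, units=units)


class TestFrameTimes:
    def make_ttl(self, starts, exposure, rate=40e3, total=0.12, high=5.0):
        y = np.zeros(int(total * rate))
        for s in starts:
            y[int(s * rate):int((s + exposure) * rate)] = high
        return Trace(y, rate, units="V")

    def test_exact_starts_and_durations(self):
        starts = [0.01, 0.03, 0.05, 0.07]
        ft = frame_times_from_exposure(self.make_ttl(starts, 0.015))
        assert len(ft) == 4
        assert np.allclose([s for s, _ in ft], starts)
        assert np.allclose([d for _, d in ft], 0.015)

    def test_initially_high_counts_as_first_frame(self):
        ft = frame_times_from_exposure(self.make_ttl([0.0, 0.02], 0.01))
        assert len(ft) == 2 and ft[0][0] == 0.0

    def test_still_high_at_end_closed_at_trace_end(self):
        ft = frame_times_from_exposure(self.make_ttl([0.10], 0.05))
        assert len(ft) == 1
        assert ft[0][1] == pytest.approx(0.02, abs=1e-4)

    def test_robust_to_10pct_noise(self):
        """0.5 V noise on a 5 V TTL stays inside the hysteresis band."""
        ttl = self.make_ttl([0.01, 0.03, 0.05], 0.015)
        rng = np.random.default_rng(0)
        noisy = Trace(ttl.samples + rng.normal(0, 0.5, ttl.n).clip(-0.9, 0.9),
                      ttl.rate, units="V")
        ft = frame_times_from_exposure(noisy)
        assert len(ft) == 3
        assert np.allclose([s for s, _ in ft], [0.01, 0.03, 0.05], atol=1e-4)

    def test_flat_trace_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="dynamic range"):
            out = frame_times_from_exposure(Trace(np.zeros(100), 1e3))
        assert out == []


class TestMembraneProperties:
    def test_recovers_known_cell_vc(self):
        cell = CellModel(Ra=10e6, Rm=100e6, Cm=30e-12)
        cmd = make_pulse()
        resp = sim_clamp_response(cell, cmd, "vc")
        p = membrane_properties(resp, cmd, "vc")
        assert p.Raccess == pytest.approx(10e6, rel=1e-3)
        assert p.Rm == pytest.approx(100e6, rel=1e-3)
        assert p.Cm == pytest.approx(30e-12, rel=1e-3)
        assert p.Rin == pytest.approx(110e6, rel=1e-3)
        assert p.tau == pytest.approx(cell.tau_vc, rel=1e-3)

    def test_small_access_resistance_limit(self):
        """As Ra shrinks, Rin approaches Rm and tau approaches Ra·Cm' regime."""
        cell = CellModel(Ra=1e6, Rm=200e6, Cm=40e-12)
        cmd = make_pulse()
        p = membrane_properties(sim_clamp_response(cell, cmd, "vc"), cmd, "vc")
        assert p.Raccess == pytest.approx(1e6, rel=5e-3)
        assert p.Rin == pytest.approx(201e6, rel=1e-3)

    def test_ic_mode_input_resistance_and_rmp(self):
        cell = CellModel(Ra=10e6, Rm=100e6, Cm=30e-12, Vrest=-70e-3)
        cmd = make_pulse(amp=-50e-12, units="A")
        resp = sim_clamp_response(cell, cmd, "ic")
        p = membrane_properties(resp, cmd, "ic")
        assert p.Rin == pytest.approx(110e6, rel=1e-3)
        assert p.resting_potential == pytest.approx(-70e-3, abs=1e-6)

    def test_noise_tolerance(self):
        cell = CellModel(Ra=12e6, Rm=150e6, Cm=25e-12, noise_sd=5e-12)
        cmd = make_pulse()
        resp = sim_clamp_response(cell, cmd, "vc", seed=4)
        p = membrane_properties(resp, cmd, "vc")
        assert p.Raccess == pytest.approx(12e6, rel=0.05)
        assert p.Rm == pytest.approx(150e6, rel=0.05)

    def test_zero_amplitude_command_rejected(self):
        cmd = make_pulse(amp=0.0)
        resp = Trace(np.zeros(cmd.n), RATE, units="A")
        with pytest.raises(ValueError, match="no step"):
            membrane_properties(resp, cmd, "vc")

    def test_bad_mode(self):
        cmd = make_pulse()
        with pytest.raises(ValueError, match="vc|ic"):
            membrane_properties(cmd, cmd, "dc")


class TestSpikesAndIV:
    def make_spike_trace(self, spike_times, total=1.0, rate=20e3):
        v = np.full(int(total * rate), -65e-3)
        for t in spike_times:
            i = int(t * rate)
            v[i:i + 10] = 30e-3
        return Trace(v, rate, units="V")

    def test_detect_spikes_exact_times(self):
        times = [0.1, 0.25, 0.4]
        got = detect_spikes(self.make_spike_trace(times))
        assert np.allclose(got, times, atol=1e-4)

    def test_refractory_merges_doublets(self):
        got = detect_spikes(self.make_spike_trace([0.1, 0.1005, 0.2]))
        assert len(got) == 2

    def test_adaptation_hand_case(self):
        """ISIs of 10, 20, 30, 40 ms give adaptation (30+40)/2 / 10 = 3.5."""
        t = np.cumsum([0.1, 0.01, 0.02, 0.03, 0.04])
        tr = self.make_spike_trace(t)
        m = iv_metrics([tr], [100e-12], (0.05, 0.9))
        assert np.allclose(m.isis, [0.01, 0.02, 0.03, 0.04], atol=1e-4)
        assert m.adaptation_ratio == pytest.approx(3.5, rel=1e-2)
        assert m.first_spike_latency == pytest.approx(0.05, abs=1e-3)

    def test_lif_family_metrics(self):
        """LIF cell: linear subthreshold Rin, constant ISIs (adaptation 1)."""
        cell = CellModel(Ra=10e6, Rm=100e6, Cm=30e-12)
        steps = [-100e-12, -50e-12, 50e-12, 300e-12]
        traces = []
        for amp in steps:
            cmd = make_pulse(amp=amp, total=1.0, start=0.1, length=0.8,
                             units="A")
            traces.append(sim_lif_response(cell, cmd, seed=0))
        m = iv_metrics(traces, steps, (0.1, 0.9))
        assert m.resting_potential == pytest.approx(cell.Vrest, abs=1e-4)
        assert m.input_resistance == pytest.approx(110e6, rel=0.02)
        assert m.tau_m == pytest.approx(cell.tau_ic, rel=0.05)
        if m.adaptation_ratio is not None:
            assert m.adaptation_ratio == pytest.approx(1.0, rel=0.05)

    def test_sag_zero_for_passive_cell(self):
        cell = CellModel(Ra=10e6, Rm=100e6, Cm=30e-12)
        steps = [-100e-12, -50e-12]
        traces = [sim_clamp_response(
            cell, make_pulse(amp=a, units="A"), "ic") for a in steps]
        m = iv_metrics(traces, steps, (0.05, 0.15))
        assert m.sag_ratio == pytest.approx(0.0, abs=0.02)

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError, match="one trace per"):
            iv_metrics([], [1e-12], (0, 1))


def make_event_trace(onsets, amp=-50e-12, tau=5e-3, rise_tau=0.5e-3,
                     total=2.0, rate=20e3, noise_sd=0.0, seed=0):
    t = np.arange(int(total * rate)) / rate
    y = np.zeros_like(t)
    for t0 in onsets:
        m = t >= t0
        dt = t[m] - t0
        y[m] += amp * (1 - np.exp(-dt / rise_tau)) * np.exp(-dt / tau)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, y.size)
    return Trace(y, rate, units="A")


class TestEventDetection:
    ONSETS = [0.2, 0.5, 0.8, 1.1, 1.4, 1.7]

    def test_clean_trace_all_events_found(self):
        tr = make_event_trace(self.ONSETS)
        ev = detect_events(tr, decay_tau_guess=5e-3)
        assert len(ev) == len(self.ONSETS)
        got = [e.onset_time for e in ev]
        assert np.max(np.abs(np.array(got) - self.ONSETS)) < 2e-3

    def test_amplitude_and_decay_recovered(self):
        amp, tau, rise = -80e-12, 6e-3, 0.5e-3
        tr = make_event_trace([0.5], amp=amp, tau=tau, rise_tau=rise)
        ev = detect_events(tr, decay_tau_guess=5e-3)
        assert len(ev) == 1
        # analytic peak of amp·(1-exp(-t/rise))·exp(-t/tau)
        t_pk = rise * np.log(1 + tau / rise)
        true_peak = amp * (1 - np.exp(-t_pk / rise)) * np.exp(-t_pk / tau)
        assert ev[0].amplitude == pytest.approx(true_peak, rel=0.05)
        assert ev[0].decay_tau == pytest.approx(6e-3, rel=0.3)
        assert 0 < ev[0].rise_time < 3e-3

    def test_snr10_recall_no_false_positives(self):
        tr = make_event_trace(self.ONSETS, amp=-50e-12, noise_sd=5e-12, seed=1)
        ev = detect_events(tr, decay_tau_guess=5e-3)
        got = np.array([e.onset_time for e in ev])
        matched = sum(np.min(np.abs(got - t0)) < 2e-3 for t0 in self.ONSETS)
        assert matched == len(self.ONSETS)
        assert len(ev) == len(self.ONSETS)

    def test_flat_noise_yields_no_events(self):
        for seed in range(10):
            tr = make_event_trace([], noise_sd=5e-12, seed=seed)
            assert detect_events(tr, decay_tau_guess=5e-3) == []

    def test_amplitude_equivariance(self):
        """Doubling the trace doubles measured amplitudes, onsets unchanged."""
        tr = make_event_trace(self.ONSETS, noise_sd=2e-12, seed=3)
        tr2 = Trace(2 * tr.samples, tr.rate, units="A")
        e1 = detect_events(tr, 5e-3)
        e2 = detect_events(tr2, 5e-3)
        assert len(e1) == len(e2)
        for a, b in zip(e1, e2):
            assert b.onset_time == pytest.approx(a.onset_time, abs=1e-3)
            assert b.amplitude == pytest.approx(2 * a.amplitude, rel=1e-6)

    def test_positive_polarity(self):
        tr = make_event_trace([0.5, 1.0], amp=+60e-12)
        ev = detect_events(tr, 5e-3, polarity="positive")
        assert len(ev) == 2 and all(e.amplitude > 0 for e in ev)

    def test_invalid_inputs(self):
        tr = make_event_trace([])
        with pytest.raises(ValueError, match="positive"):
            detect_events(tr, -1e-3)
        with pytest.raises(ValueError, match="polarity"):
            detect_events(tr, 5e-3, polarity="both")
        with pytest.raises(ValueError, match="shorter"):
            detect_events(Trace(np.zeros(100), 20e3), 5e-3)


class TestChargeTransfer:
    def test_rectangular_pulse_hand_case(self):
        """100 pA for 50 ms is 5 pC."""
        y = np.zeros(20000)
        y[2000:3000] = 100e-12  # 50 ms at 20 kHz
        tr = Trace(y, 20e3, units="A")
        q = charge_transfer(tr, (0.05, 0.25), (0.0, 0.05))
        assert q == pytest.approx(5e-12, rel=1e-3)

    def test_exponential_event_charge_is_amp_tau(self):
        tr = make_event_trace([0.5], amp=-50e-12, tau=5e-3, rise_tau=1e-9)
        q = charge_transfer(tr, (0.45, 1.5), (0.0, 0.4))
        assert q == pytest.approx(-50e-12 * 5e-3, rel=1e-2)

    def test_baseline_offset_cancels(self):
        tr = make_event_trace([0.5], amp=-50e-12)
        shifted = Trace(tr.samples - 30e-12, tr.rate, units="A")
        q0 = charge_transfer(tr, (0.45, 1.5), (0.0, 0.4))
        q1 = charge_transfer(shifted, (0.45, 1.5), (0.0, 0.4))
        assert q1 == pytest.approx(q0, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-200e-12, -10e-12), st.floats(-200e-12, -10e-12))
    def test_additivity(self, a1, a2):
        t1 = make_event_trace([0.5], amp=a1)
        t2 = make_event_trace([0.9], amp=a2)
        both = Trace(t1.samples + t2.samples, t1.rate, units="A")
        w, b = (0.4, 1.6), (0.0, 0.3)
        assert charge_transfer(both, w, b) == pytest.approx(
            charge_transfer(t1, w, b) + charge_transfer(t2, w, b), rel=1e-6)


class TestMapClassification:
    def null_sites(self, n, lam, rng, n_trials=5, base_w=0.5, test_w=0.05):
        return [MapSite(position=(i * 1e-5, 0.0), n_trials=n_trials,
                        spontaneous_count=int(rng.poisson(lam * base_w * n_trials)),
                        test_count=int(rng.poisson(lam * test_w * n_trials)))
                for i in range(n)]

    def test_null_maps_rarely_flagged(self, rng):
        false_rates = []
        for _ in range(100):
            sites = self.null_sites(30, lam=2.0, rng=rng)
            classify_map_sites(sites, 0.05, 0.5, alpha=0.05)
            false_rates.append(np.mean([s.evoked_flag for s in sites]))
        assert np.mean(false_rates) <= 0.05

    def test_strong_responses_all_flagged(self, rng):
        sites = self.null_sites(30, lam=2.0, rng=rng)
        for s in sites[:10]:
            s.test_count += 5 * s.n_trials  # +5 evoked events per trial
        classify_map_sites(sites, 0.05, 0.5, alpha=0.05)
        assert all(s.evoked_flag for s in sites[:10])
        assert all(s.p_value < 0.05 for s in sites[:10])

    def test_zero_spontaneous_rate_degenerate_null(self):
        sites = [MapSite((0, 0), n_trials=3, spontaneous_count=0, test_count=2),
                 MapSite((1e-5, 0), n_trials=3, spontaneous_count=0,
                         test_count=0)]
        classify_map_sites(sites, 0.05, 0.5)
        assert sites[0].evoked_flag and sites[0].p_value == 0.0
        assert not sites[1].evoked_flag and sites[1].p_value == 1.0

    def test_metric_variants(self):
        sites = [MapSite((0, 0), n_trials=4, spontaneous_count=1, test_count=8)]
        classify_map_sites(sites, 0.05, 0.5, metric="mean_count")
        assert sites[0].metric_value == pytest.approx(2.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            MapSite((0, 0), spontaneous_count=-1)

    def test_exports(self, tmp_path, rng):
        import csv
        import sqlite3
        sites = classify_map_sites(self.null_sites(5, 2.0, rng), 0.05, 0.5)
        export_map_csv(sites, tmp_path / "m.csv")
        with open(tmp_path / "m.csv") as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 6 and rows[0][0] == "x"
        export_map_sqlite(sites, tmp_path / "m.db")
        con = sqlite3.connect(tmp_path / "m.db")
        assert con.execute("SELECT COUNT(*) FROM map_sites").fetchone()[0] == 5
        con.close()
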