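"""Filtering, event detection, segmentation and measurement."""

import numpy as np
import pytest

import mechanops as m
from mechanops.errors import ParameterError, SegmentationError
from mechanops.pulses import detect_events, lowpass_filter, measure_event, segment_event


class TestLowpass:
    def test_dc_gain_unity(self, geometry):
        t = np.arange(5000) / 50_000.0
        tr = m.RawTrace(t=t, i=np.full_like(t, 0.9))
        out = lowpass_filter(tr, 5000.0)
        np.testing.assert_allclose(out.i, 0.9, rtol=1e-12)

    def test_sinusoid_above_cutoff_attenuated(self):
        fs, cutoff = 50_000.0, 2_000.0
        t = np.arange(int(fs)) / fs
        tr = m.RawTrace(t=t, i=1.0 + 0.01 * np.sin(2 * np.pi * 10 * cutoff * t))
        out = lowpass_filter(tr, cutoff)
        mid = out.i[len(t) // 4 : -len(t) // 4]
        atten = (mid - 1.0).std() / (0.01 / np.sqrt(2))
        assert atten < 0.1  # ≥ 20 dB

    def test_noise_sd_reduced(self):
        rng = np.random.default_rng(4)
        fs = 50_000.0
        t = np.arange(int(fs)) / fs
        noise = rng.normal(0, 1e-3, len(t))
        out = lowpass_filter(m.RawTrace(t=t, i=1.0 + noise), 5000.0)
        assert (out.i - 1.0).std() < noise.std()

    def test_cutoff_above_nyquist_rejected(self):
        t = np.arange(1000) / 50_000.0
        tr = m.RawTrace(t=t, i=np.ones_like(t))
        with pytest.raises(ParameterError):
            lowpass_filter(tr, 30_000.0)


class TestDetection:
    def test_all_simulated_events_found(self, small_run, geometry, acquisition):
        cfg, trace, truths, _, _ = small_run
        work = lowpass_filter(trace, acquisition.lowpass_cutoff)
        windows = detect_events(work, geometry, acquisition)
        assert len(windows) == len(truths)
        for w, t in zip(windows, truths):
            assert w.t_start <= t.boundaries[0] <= t.boundaries[-1] <= w.t_end + 1e-9
            assert not w.coincidence and not w.truncated

    def test_windows_disjoint_and_sorted(self, small_run, geometry, acquisition):
        _, trace, _, _, _ = small_run
        work = lowpass_filter(trace, acquisition.lowpass_cutoff)
        windows = detect_events(work, geometry, acquisition)
        for a, b in zip(windows, windows[1:]):
            assert a.i1 <= b.i0

    def test_constant_trace_yields_nothing(self, geometry, acquisition):
        t = np.arange(20_000) / acquisition.sampling_rate
        tr = m.RawTrace(t=t, i=np.ones_like(t))
        assert detect_events(tr, geometry, acquisition) == []

    def test_coincidence_rejected_and_counts_conserved(self, geometry, acquisition):
        cfg = m.SimulationConfig(
            geometry=geometry,
            acquisition=acquisition,
            n_cells=10,
            noise_sd=0.0,
            seed=5,
            coincidence_pairs=1,
        )
        trace, truths = m.simulate_trace(cfg)
        records, rejects = m.extract_pulses(trace, geometry, acquisition)
        # the two overlapping cells form one composite window, rejected
        assert len(records) == 8
        assert len(rejects) >= 1
        work = lowpass_filter(trace, acquisition.lowpass_cutoff)
        windows = detect_events(work, geometry, acquisition)
        assert len(windows) == len(records) + len(rejects)


class TestSegmentation:
    def test_counts_match_geometry(self, small_run, geometry, acquisition):
        _, trace, _, records, _ = small_run
        rec = records[0]
        assert len(rec.pre_pulses) == geometry.n_pre_pairs
        assert len(rec.post_pulses) == geometry.n_post_pairs
        assert rec.contraction.segment_kind == "contraction"

    def test_pre_pore_amplitudes_equal_and_contraction_deepest(self, small_run):
        _, _, _, records, _ = small_run
        for rec in records:
            pre_amps = [s.dI for s in rec.pre_pulses]
            assert np.ptp(pre_amps) < 1e-6 * np.mean(pre_amps)
            assert rec.dI_c > max(pre_amps)

    def test_two_plateau_window_rejected(self, geometry, acquisition):
        """A run pattern with too few plateaus cannot be segmented."""
        fs = acquisition.sampling_rate
        n = 30_000
        i = np.ones(n)
        i[5000:5100] -= 1e-3
        i[5300:6800] -= 3e-3
        tr = m.RawTrace(t=np.arange(n) / fs, i=i)
        windows = detect_events(tr, geometry, acquisition)
        assert len(windows) == 1
        with pytest.raises(SegmentationError):
            segment_event(tr, windows[0], geometry, acquisition)


class TestMeasurement:
    def test_instant_cell_has_zero_recovery(self, small_run, truth_class="instant"):
        _, _, truths, records, _ = small_run
        for rec, tr in zip(records, truths):
            if tr.recovery_class_true == "instant":
                assert rec.dT_r == 0.0 and not rec.dT_r_censored

    def test_transient_recovery_within_one_pore_spacing(
        self, geometry, acquisition
    ):
        cfg = m.SimulationConfig(
            geometry=geometry,
            acquisition=acquisition,
            n_cells=12,
            noise_sd=0.0,
            seed=13,
            recovery_mix={"instant": 0.0, "transient": 1.0, "prolonged": 0.0},
        )
        trace, truths = m.simulate_trace(cfg)
        records, _ = m.extract_pulses(trace, geometry, acquisition)
        spacing_ms = (geometry.node_length + geometry.pore_length) / 50.0
        assert len(records) == len(truths)
        for rec, tr in zip(records, truths):
            assert 0 < rec.dT_r <= tr.window_ms
            assert abs(rec.dT_r - tr.dT_r_true) <= spacing_ms

    def test_prolonged_cell_censored_at_window(self, geometry, acquisition):
        cfg = m.SimulationConfig(
            geometry=geometry,
            acquisition=acquisition,
            n_cells=5,
            noise_sd=0.0,
            seed=17,
            recovery_mix={"instant": 0.0, "transient": 0.0, "prolonged": 1.0},
        )
        trace, truths = m.simulate_trace(cfg)
        records, _ = m.extract_pulses(trace, geometry, acquisition)
        assert len(records) == 5
        for rec in records:
            assert rec.dT_r_censored
            assert rec.dT_r == pytest.approx(rec.window_ms)

    def test_inconsistent_event_rejected(self, small_run):
        """A 'contraction' shallower than the pores is not a valid cell pulse."""
        _, _, _, records, _ = small_run
        rec = records[0]
        bad = [
            m.SubPulse(s.segment_kind, s.index, s.t_start, s.t_end, dI=s.dI * 0.1)
            if s.segment_kind == "contraction"
            else s
            for s in (*rec.pre_pulses, rec.contraction, *rec.post_pulses)
        ]
        with pytest.raises(m.errors.MechanopsError):
            measure_event(bad)


class TestEndToEnd:
    def test_noise_free_round_trip(self, small_run, geometry):
        """Simulator → pipeline recovers amplitudes, times and classes."""
        cfg, _, truths, records, rejects = small_run
        assert rejects == []
        assert len(records) == cfg.n_cells
        for rec, tr in zip(records, truths):
            assert rec.dI_np == pytest.approx(tr.dI_np_true, rel=1e-6)
            assert rec.dI_c == pytest.approx(tr.dI_c_true, rel=1e-6)
            assert abs(rec.dT_cont - tr.dT_cont_true) < 1e3 / cfg.acquisition.sampling_rate
            measured = m.classify_recovery(
                0.0 if rec.dT_r_censored else rec.dT_r, rec.window_ms, rec.dT_r_censored
            )
            assert measured == tr.recovery_class_true

    def test_phenotype_chain_recovers_diameter_and_speed(self, small_run, geometry):
        _, _, truths, records, _ = small_run
        for rec, tr in zip(records, truths):
            ph = m.phenotype_from_record(rec, geometry)
            assert ph.D_cell == pytest.approx(tr.D_cell_true, rel=1e-6)
            assert ph.U_flow == pytest.approx(tr.speed_node, rel=0.02)
            assert ph.recovery_class == tr.recovery_class_true
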