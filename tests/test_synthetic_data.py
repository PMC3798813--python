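"""Simulator correctness: ground-truth exactness, determinism, failure modes."""

import numpy as np
import pytest

from echotrace.errors import ValidationError
from echotrace.synthetic_data import (
    InterfaceCircuit,
    MWaveGridParams,
    SpringSceneParams,
    TwitchSceneParams,
    simulate_interface_signals,
    simulate_mwave_grid,
    simulate_spring_sequence,
    simulate_twitch_sequence,
    spring_structure_centroids,
    twitch_pulse,
)


class TestSpringScene:
    def test_frame_count_and_ground_truth_formula(self):
        p = SpringSceneParams(duration_s=2.0, peak_to_peak_mm=1.4, frequency_hz=1.0, seed=1)
        seq, gt = simulate_spring_sequence(p)
        assert seq.n_frames == round(2.0 * 80) == gt.n_frames
        t = np.arange(seq.n_frames) / 80.0
        expected = 10.0 + 0.7 * np.sin(2 * np.pi * 1.0 * t)
        np.testing.assert_allclose(gt.length_mm, expected, rtol=0, atol=1e-12)
        # peak-to-peak range of the truth equals the commanded amplitude
        assert gt.length_mm.max() - gt.length_mm.min() == pytest.approx(1.4, abs=1e-3)

    def test_max_frame_to_frame_edge_displacement(self):
        """d/dt of the sine bounds the per-frame motion: D/2 * 2 pi f / rate."""
        p = SpringSceneParams(duration_s=2.0, peak_to_peak_mm=1.4, frequency_hz=1.0, seed=1)
        _, gt = simulate_spring_sequence(p)
        step = np.abs(np.diff(gt.length_mm)).max()
        assert step == pytest.approx(0.7 * 2 * np.pi * 1.0 / 80.0, rel=0.01)

    def test_zero_amplitude_freezes_the_scene(self):
        p = SpringSceneParams(duration_s=0.25, peak_to_peak_mm=0.0, frequency_hz=1.0, seed=3)
        seq, gt = simulate_spring_sequence(p)
        assert np.all(seq.frames == seq.frames[0])
        assert np.all(gt.length_mm == gt.length_mm[0])

    def test_deterministic_regeneration(self):
        p = lambda s: SpringSceneParams(duration_s=0.25, seed=s)  # noqa: E731
        a, _ = simulate_spring_sequence(p(9))
        b, _ = simulate_spring_sequence(p(9))
        c, _ = simulate_spring_sequence(p(10))
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_nyquist_and_calibration_rejection(self):
        with pytest.raises(ValidationError):
            SpringSceneParams(frequency_hz=40.0, frame_rate_hz=80.0)
        with pytest.raises(ValidationError):
            SpringSceneParams(calib_mm_per_px=(0.0, 0.05))

    def test_structure_centroids_match_ground_truth(self):
        """Axial separation of the rendered end structures (noiseless layer)
        tracks the emitted length to within 0.02 mm."""
        p = SpringSceneParams(duration_s=0.5, peak_to_peak_mm=1.4, frequency_hz=2.0, seed=2)
        _, gt = simulate_spring_sequence(p)
        frames = [0, 5, 10, 15, 25, 35]
        cents = spring_structure_centroids(p, frames)
        sep = cents[:, 1] - cents[:, 0]
        np.testing.assert_allclose(sep, gt.length_mm[frames], atol=0.02)

    def test_displacement_field_endpoints(self):
        p = SpringSceneParams(duration_s=0.5, peak_to_peak_mm=1.0, frequency_hz=2.0, seed=2)
        _, gt = simulate_spring_sequence(p)
        y_top = p.axial_margin_mm
        y_bot = y_top + p.rest_length_mm
        pts = np.array([[y_bot, 3.0], [y_top, 3.0]])
        for f in (3, 11, 27):
            d = gt.displacement(f, pts)
            s = gt.length_mm[f] - p.rest_length_mm
            assert d[0, 0] == pytest.approx(0.0, abs=1e-12)  # fixed end
            assert d[1, 0] == pytest.approx(-s, abs=1e-9)  # driven end
            assert np.all(d[:, 1] == 0)


class TestTwitchScene:
    def test_stimulus_count_1pps_20s(self):
        p = TwitchSceneParams(duration_s=20.0, stim_rate_pps=1.0)
        assert len(p.stimulus_onsets_s) == 20

    def test_zero_amplitudes_constant_truth(self):
        p = TwitchSceneParams(
            duration_s=0.5, shortening_mm=0.0, thickening_mm=0.0, seed=4
        )
        seq, gt, _ = simulate_twitch_sequence(p)
        assert np.all(gt.length_mm == gt.length_mm[0])
        assert np.all(gt.thickness_mm == gt.thickness_mm[0])
        assert np.all(seq.frames == seq.frames[0])

    def test_shortening_reaches_commanded_amplitude(self):
        p = TwitchSceneParams(duration_s=2.0, shortening_mm=1.0, seed=4)
        _, gt, _ = simulate_twitch_sequence(p)
        t = np.arange(p.n_frames) / p.frame_rate_hz
        pulse = twitch_pulse(t, p.stimulus_onsets_s, p.tau_rise_s, p.tau_decay_s)
        assert gt.length_mm.min() == pytest.approx(
            p.resting_muscle_length_mm - 1.0 * pulse.max(), abs=1e-12
        )
        assert pulse.max() == pytest.approx(1.0, abs=0.01)

    def test_thickness_equals_deformed_aponeurosis_gap(self):
        p = TwitchSceneParams(duration_s=1.0, seed=4)
        _, gt, seg = simulate_twitch_sequence(p)
        # material points on the two aponeuroses at the scene centre
        cx = p.lateral_width_mm / 2
        pts = np.array(
            [[p.superficial_depth_mm, cx],
             [p.superficial_depth_mm + p.resting_thickness_mm, cx]]
        )
        for f in (0, 10, 20, 40):
            d = gt.displacement(f, pts)
            gap = (pts[1, 0] + d[1, 0]) - (pts[0, 0] + d[0, 0])
            assert gap == pytest.approx(gt.thickness_mm[f], abs=1e-9)
        # segmentation sanity: deep strictly below superficial
        assert np.all(seg.deep[:, 0] > seg.superficial[:, 0])

    def test_folding_deformation_rejected(self):
        with pytest.raises(ValidationError):
            TwitchSceneParams(shortening_mm=11.0, resting_thickness_mm=14.0)
        with pytest.raises(ValidationError):
            TwitchSceneParams(thickening_mm=-20.0, resting_thickness_mm=14.0)

    def test_twitch_pulse_shape(self):
        with pytest.raises(ValidationError):
            twitch_pulse(np.arange(5), [0.0], tau_rise_s=0.1, tau_decay_s=0.05)
        t = np.linspace(0, 1, 2000)
        pulse = twitch_pulse(t, [0.0], 0.025, 0.09)
        assert pulse.max() == pytest.approx(1.0, abs=1e-4)
        assert np.all(pulse >= 0)
        # unimodal: single sign change of the derivative
        assert np.sum(np.diff(np.sign(np.diff(pulse))) != 0) == 1


class TestMWaveGrid:
    def test_channel_count_and_triggers(self, mwave_rec):
        assert mwave_rec.n_channels == 32  # 4 columns x 8 rows
        assert len(mwave_rec.trigger_samples) == 20  # 1 pps for 20 s
        assert np.all(np.diff(mwave_rec.trigger_samples) == 2048)

    def test_noiseless_epochs_identical(self):
        rec = simulate_mwave_grid(MWaveGridParams(duration_s=6.0, noise_rms_uV=0.0, seed=0))
        from echotrace.emg_pipeline import average_template, extract_epochs

        epochs = extract_epochs(rec, epoch_ms=40.0)
        assert np.all(epochs == epochs[:, :1, :])
        tpl = average_template(epochs, n_epochs=epochs.shape[1])
        np.testing.assert_allclose(tpl, epochs[:, 0, :], rtol=1e-12, atol=1e-12)

    def test_open_contact_channel_is_loud(self):
        p = MWaveGridParams(duration_s=6.0, seed=1, bad_channels={3: "open_contact"})
        rec = simulate_mwave_grid(p)
        rms = np.sqrt(np.mean(rec.samples**2, axis=1))
        assert rms[3] >= 20 * p.noise_rms_uV

    def test_short_circuit_pair_is_sample_identical(self):
        p = MWaveGridParams(duration_s=6.0, seed=1, bad_channels={6: "short_circuit_pair"})
        rec = simulate_mwave_grid(p)
        assert np.array_equal(rec.samples[6], rec.samples[7])

    def test_validation(self):
        with pytest.raises(ValidationError):
            MWaveGridParams(duration_s=0.3)
        with pytest.raises(ValidationError):
            MWaveGridParams(bad_channels={40: "open_contact"})
        with pytest.raises(ValidationError):
            MWaveGridParams(bad_channels={1: "on_fire"})

    def test_deterministic(self):
        a = simulate_mwave_grid(MWaveGridParams(duration_s=3.0, seed=2))
        b = simulate_mwave_grid(MWaveGridParams(duration_s=3.0, seed=2))
        np.testing.assert_array_equal(a.samples, b.samples)


class TestInterfaceSignals:
    def test_resistive_circuit(self):
        c = InterfaceCircuit(R_series_ohm=5e4, R_parallel_ohm=0.0, C_parallel_F=0.0)
        z = c.impedance([10.0, 100.0, 1000.0])
        np.testing.assert_allclose(np.abs(z), 5e4)
        np.testing.assert_allclose(np.angle(z), 0.0)

    def test_pure_capacitor_closed_form(self):
        c = InterfaceCircuit(R_series_ohm=0.0, R_parallel_ohm=np.inf, C_parallel_F=10e-9)
        f = 1.0 / (2 * np.pi * 10e-9 * 1e5)  # ~159.15 Hz where |Z| = 100 kOhm
        z = complex(c.impedance(f))
        assert abs(z) == pytest.approx(1e5, rel=1e-9)
        assert np.degrees(np.angle(z)) == pytest.approx(-90.0, abs=1e-9)

    def test_default_sweep_spans_10_to_1000(self):
        sig = simulate_interface_signals(InterfaceCircuit(), seed=0)
        freqs = sorted(sig)
        assert freqs[0] == 10.0 and freqs[-1] == 1000.0
        # every record holds at least 10 full cycles
        for f, (v, i) in sig.items():
            assert v.size / 10000.0 >= 10.0 / f

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValidationError):
            simulate_interface_signals(InterfaceCircuit(), freqs_hz=[0.0])
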