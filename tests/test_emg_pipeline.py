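"""EMG chain: zero-phase filtering, epoching, template averaging with CLT
noise reduction, NMSE maps and channel screening on injected faults."""

import numpy as np
import pytest
import scipy.stats as sps

from echotrace.containers import EMGRecording, GridGeometry
from echotrace.emg_pipeline import (
    average_template,
    bandpass,
    extract_epochs,
    mwave_templates,
    screen_channels,
    template_nmse_map,
)
from echotrace.errors import AnalysisError, ValidationError
from echotrace.synthetic_data import MWaveGridParams, simulate_mwave_grid


def _rec(samples, fs=2048.0, triggers=()):
    n_ch = samples.shape[0]
    rows = n_ch if n_ch <= 8 else 8
    grid = GridGeometry(rows=rows, cols=n_ch // rows)
    return EMGRecording(samples=samples, fs_hz=fs, grid=grid,
                        trigger_samples=np.asarray(triggers, dtype=int))


class TestBandpass:
    def test_dc_offset_removed(self):
        rec = _rec(np.full((1, 8192), 500.0), fs=2048.0)
        out = bandpass(rec)
        assert abs(out.samples.mean()) < 0.5  # < 1e-3 of the 500 uV offset

    def test_passband_sine_amplitude_preserved(self):
        fs = 2048.0
        t = np.arange(int(4 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 100.0 * t)[None, :], fs=fs)
        out = bandpass(rec)
        mid = out.samples[0, 2048:-2048]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.02)

    def test_zero_phase_keeps_pulse_peak_index(self):
        fs = 2048.0
        x = np.zeros((1, 4096))
        center = 2048
        x[0] = np.exp(-0.5 * ((np.arange(4096) - center) / 12.0) ** 2)
        out = bandpass(_rec(x, fs=fs))
        assert np.argmax(out.samples[0]) == center

    def test_invalid_band_edges(self):
        rec = _rec(np.zeros((1, 4096)))
        with pytest.raises(ValidationError):
            bandpass(rec, low_hz=450.0, high_hz=20.0)
        with pytest.raises(ValidationError):
            bandpass(rec, low_hz=20.0, high_hz=2000.0)

    def test_triggers_untouched(self, mwave_rec):
        out = bandpass(mwave_rec)
        np.testing.assert_array_equal(out.trigger_samples, mwave_rec.trigger_samples)


class TestEpochs:
    def test_epoch_length_82_at_2048(self, mwave_rec):
        epochs = extract_epochs(mwave_rec, epoch_ms=40.0)
        assert epochs.shape == (32, 20, 82)

    def test_epoch_length_40_at_1000(self):
        rec = _rec(np.zeros((1, 3000)), fs=1000.0, triggers=[100, 1100])
        assert extract_epochs(rec, epoch_ms=40.0).shape[-1] == 40

    def test_overrunning_trigger_skipped_with_warning(self):
        rec = _rec(np.zeros((1, 2048)), triggers=[0, 500, 2048 - 30])
        with pytest.warns(UserWarning, match="skipped 1"):
            epochs = extract_epochs(rec, epoch_ms=40.0)
        assert epochs.shape[1] == 2

    def test_no_triggers_is_an_error(self):
        with pytest.raises(AnalysisError):
            extract_epochs(_rec(np.zeros((1, 2048))))


class TestAverageTemplate:
    def test_identical_epochs_average_to_one_epoch(self):
        w = np.sin(np.linspace(0, 3, 82))
        epochs = np.tile(w, (1, 20, 1))
        np.testing.assert_allclose(average_template(epochs, 20)[0], w, rtol=1e-12)
        np.testing.assert_array_equal(average_template(epochs, 1)[0], w)

    def test_too_few_epochs_reports_count(self):
        with pytest.raises(ValidationError, match="5"):
            average_template(np.zeros((1, 5, 82)), n_epochs=20)

    def test_noise_reduction_follows_sqrt_n(self):
        """Averaging n epochs divides the residual noise RMS by sqrt(n):
        the log-log slope of residual RMS vs n is -0.5 within 10%."""
        rng = np.random.default_rng(0)
        w = 50 * np.sin(np.linspace(0, 2 * np.pi, 82))
        ns = np.array([1, 2, 5, 10, 20, 50])
        resid = []
        for n in ns:
            runs = []
            for _ in range(60):
                epochs = w + rng.normal(0, 5.0, size=(n, 82))
                runs.append(np.sqrt(np.mean((epochs.mean(axis=0) - w) ** 2)))
            resid.append(np.mean(runs))
        slope = np.polyfit(np.log(ns), np.log(resid), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.05)

    def test_template_noise_matches_clt_prediction(self):
        """Residual template noise ~ sigma / sqrt(20) (within 20%)."""
        rng = np.random.default_rng(1)
        sigma = 8.0
        w = 100 * np.sin(np.linspace(0, 2 * np.pi, 82))
        resid = []
        for _ in range(100):
            epochs = w + rng.normal(0, sigma, size=(20, 82))
            resid.append(np.sqrt(np.mean((epochs.mean(axis=0) - w) ** 2)))
        assert np.mean(resid) == pytest.approx(sigma / np.sqrt(20), rel=0.2)


class TestNMSEMap:
    @staticmethod
    def _tplset(waveforms):
        from echotrace.emg_pipeline import MWaveTemplateSet
        from echotrace.containers import default_channel_map

        grid = GridGeometry()
        return MWaveTemplateSet(
            waveforms=waveforms, n_epochs_averaged=20, epoch_ms=40.0,
            grid=grid, channel_map=default_channel_map(grid),
        )

    def test_identical_sets_all_zero(self):
        w = np.random.default_rng(2).normal(size=(32, 82))
        m = template_nmse_map(self._tplset(w), self._tplset(w.copy()))
        np.testing.assert_allclose(m.values, 0.0)
        assert m.central_mean == 0.0 and m.lateral_mean == 0.0

    def test_scaled_set_gives_one_percent(self):
        """f = 1.1 g on every channel: NMSE = (0.1)^2 * 100 = 1%."""
        w = np.random.default_rng(3).normal(size=(32, 82))
        m = template_nmse_map(self._tplset(1.1 * w), self._tplset(w))
        np.testing.assert_allclose(m.values, 1.0, rtol=1e-9)

    def test_noise_level_matches_power_oracle(self):
        """Independent template noise sigma/sqrt(20) in both trials gives
        NMSE ~ 2 sigma^2 N / (20 sum g^2) * 100 (within a factor 2)."""
        rng = np.random.default_rng(4)
        g = 100 * np.sin(np.linspace(0, 2 * np.pi, 82))
        sigma = 10.0
        vals = []
        for _ in range(200):
            f_t = g + rng.normal(0, sigma / np.sqrt(20), 82)
            g_t = g + rng.normal(0, sigma / np.sqrt(20), 82)
            vals.append(100 * np.sum((f_t - g_t) ** 2) / np.sum(g_t**2))
        oracle = 100 * 2 * sigma**2 / 20 * 82 / np.sum(g**2)
        assert np.mean(vals) == pytest.approx(oracle, rel=0.5)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        wa, wb = rng.normal(size=(2, 32, 82))
        m = template_nmse_map(self._tplset(wa), self._tplset(wb))
        perm = rng.permutation(32)
        from echotrace.containers import default_channel_map

        base_map = default_channel_map(GridGeometry())
        sa, sb = self._tplset(wa[perm]), self._tplset(wb[perm])
        sa.channel_map = {i: base_map[perm[i]] for i in range(32)}
        sb.channel_map = dict(sa.channel_map)
        mp = template_nmse_map(sa, sb)
        np.testing.assert_allclose(mp.values, m.values[perm])
        assert mp.central_mean == pytest.approx(m.central_mean)

    def test_zero_reference_channel_excluded(self):
        rng = np.random.default_rng(6)
        w = rng.normal(size=(32, 82))
        g = w.copy()
        g[4] = 0.0
        m = template_nmse_map(self._tplset(w), self._tplset(g))
        assert 4 in m.excluded
        assert np.isnan(m.values[4])
        assert np.isfinite(m.grand_mean)


class TestScreening:
    def test_clean_grid_all_ok(self, mwave_rec):
        q = screen_channels(mwave_rec)
        assert q.flags == ["ok"] * 32

    def test_injected_faults_flagged(self):
        p = MWaveGridParams(
            duration_s=6.0, seed=9,
            bad_channels={2: "open_contact", 10: "short_circuit_pair",
                          25: "artifact_burst"},
        )
        q = screen_channels(simulate_mwave_grid(p))
        assert q.flags[2] == "open_contact"
        assert q.flags[10] == "short_circuit" and q.flags[11] == "short_circuit"
        assert q.flags[25] == "artifact"
        others = [f for i, f in enumerate(q.flags) if i not in (2, 10, 11, 25)]
        assert others == ["ok"] * len(others)

    def test_powerline_detected(self):
        rng = np.random.default_rng(7)
        fs = 2048.0
        t = np.arange(int(4 * fs)) / fs
        samples = rng.normal(0, 5.0, (32, t.size))
        samples[17] += 60.0 * np.sin(2 * np.pi * 50.0 * t)
        q = screen_channels(_rec(samples, fs=fs))
        assert q.flags[17] == "powerline"


def test_central_lateral_null_calibration():
    """With a flat spatial profile two same-condition trials show no central
    vs lateral difference: the paired-t p-value is uniform over 200 seeded
    replicates (KS against uniform, p > 0.01)."""
    from echotrace.stats import paired_t

    base = dict(
        duration_s=4.0, first_stim_s=0.3, stim_rate_pps=1.0,
        profile_sigma=(1e6, 1e6), noise_rms_uV=30.0,
    )
    ps = []
    ss = np.random.SeedSequence(2024).spawn(400)
    for k in range(200):
        r1 = simulate_mwave_grid(MWaveGridParams(seed=ss[2 * k], **base))
        r2 = simulate_mwave_grid(MWaveGridParams(seed=ss[2 * k + 1], **base))
        t1 = mwave_templates(r1, n_epochs=3)
        t2 = mwave_templates(r2, n_epochs=3)
        m = template_nmse_map(t2, t1)
        grid_vals = m.as_grid()
        central = grid_vals[:, list(m.central_cols)].ravel()
        lateral = grid_vals[:, list(m.lateral_cols)].ravel()
        ps.append(paired_t(central, lateral)[1])
    assert sps.kstest(ps, "uniform").pvalue > 0.01
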