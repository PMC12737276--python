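import numpy as np
import pytest
from scipy import stats

from ecogsleep import spectral
from ecogsleep import spindles as sp
from ecogsleep import synthdata as sd
from ecogsleep.io import Hypnogram


class TestDespike:
    def test_clean_signal_unchanged(self, rng):
        x = rng.standard_normal(5000)
        np.testing.assert_array_equal(sp.despike(x, 1024.0), x)

    def test_single_spike_interpolated_to_neighbor_mean(self, rng):
        # fs = 100 makes the +/-2 ms pad round to zero samples
        x = rng.standard_normal(1000)
        sd_r = 1.4826 * np.median(np.abs(x - np.median(x)))
        x[500] = 8 * sd_r
        out = sp.despike(x, 100.0)
        assert out[500] == pytest.approx((x[499] + x[501]) / 2)

    def test_simulator_spikes_removed(self):
        cfg = sd.SimConfig(
            n_channels=1, fs=1024.0, duration=120.0, spike_rate=5.0,
            spindle_rate=0.0, seed=2,
        )
        rec, truth = sd.simulate_recording(cfg)
        assert truth.spike_events  # something to remove
        out = sp.despike(rec.samples[0], 1024.0)
        resid = out - np.mean(out)
        assert np.max(np.abs(resid)) <= 6.5 * np.std(out)

    def test_quality_warning_when_many_flagged(self):
        x = np.zeros(1000)
        x[::3] = 100.0
        x += np.random.default_rng(0).standard_normal(1000) * 0.1
        with pytest.warns(UserWarning, match="quality"):
            sp.despike(x, 1024.0)

    def test_idempotent(self, rng):
        x = rng.standard_normal(5000)
        x[1000] += 50
        once = sp.despike(x, 1024.0)
        twice = sp.despike(once, 1024.0)
        np.testing.assert_allclose(once, twice, atol=1e-10)


class TestResample:
    def test_2048_halves_length(self, rng):
        x = rng.standard_normal(2048 * 3)
        y = sp.resample_1024(x, 2048.0)
        assert abs(len(y) - len(x) // 2) <= 1

    def test_sinusoid_amplitude_preserved(self):
        fs = 2048.0
        t = np.arange(int(5 * fs)) / fs
        x = np.sin(2 * np.pi * 12.0 * t)
        y = sp.resample_1024(x, fs)
        core = y[1024:-1024]
        assert abs(np.max(core) - 1.0) <= 0.01

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="contract"):
            sp.resample_1024(np.zeros(100), 512.0)


class TestDetrendHp:
    def test_constant_removed(self):
        y = sp.detrend_hp(np.full(4096, 5.0), 1024.0)
        assert np.max(np.abs(y)) < 1e-6

    def test_12hz_passes(self):
        fs = 1024.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 12.0 * t)
        y = sp.detrend_hp(x, fs)
        core = slice(int(fs), int(-fs))
        db = 20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert abs(db) <= 1.0

    def test_very_slow_oscillation_attenuated(self):
        fs = 1024.0
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        y = sp.detrend_hp(x, fs)
        core = slice(int(5 * fs), int(-5 * fs))
        db = 20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert db <= -20.0


class TestIca:
    def test_blind_source_recovery(self, rng):
        n_src, n_ch, n = 32, 64, 4000
        sources = rng.laplace(size=(n_src, n))
        mix = rng.standard_normal((n_ch, n_src))
        data = mix @ sources
        comps, mixing, unmixing = sp.ica_decompose(data, 32, seed=0)
        # each true source should correlate >= 0.95 with some component
        c = np.corrcoef(np.vstack([sources, comps]))[:n_src, n_src:]
        best = np.max(np.abs(c), axis=1)
        assert np.min(best) >= 0.95

    def test_reconstruction_projection(self, rng):
        data = rng.standard_normal((40, 3000))
        comps, mixing, _ = sp.ica_decompose(data, 32, seed=1)
        recon = mixing @ comps + data.mean(axis=1, keepdims=True)
        resid_energy = np.sum((data - recon) ** 2)
        total_energy = np.sum((data - data.mean(axis=1, keepdims=True)) ** 2)
        # residual bounded by the energy outside the retained 32-dim subspace
        u, s, _ = np.linalg.svd(data - data.mean(axis=1, keepdims=True),
                                full_matrices=False)
        discarded = np.sum(s[32:] ** 2)
        assert resid_energy <= discarded * 1.01 + 1e-6 * total_energy

    def test_deterministic_under_seed(self, rng):
        data = rng.standard_normal((34, 2000))
        _, _, u1 = sp.ica_decompose(data, 32, seed=7)
        _, _, u2 = sp.ica_decompose(data, 32, seed=7)
        np.testing.assert_allclose(u1, u2, atol=1e-8)

    def test_too_few_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="channels"):
            sp.ica_decompose(rng.standard_normal((8, 1000)), 32)


class TestSigmaBandpass:
    def test_13hz_preserved(self):
        fs = 1024.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * 13.0 * t)
        y = sp.sigma_bandpass(x, fs)
        core = slice(int(fs), int(-fs))
        db = 20 * np.log10(np.std(y[core]) / np.std(x[core]))
        assert abs(db) <= 1.0

    @pytest.mark.parametrize("freq", [4.0, 5.0, 25.0])
    def test_out_of_band_attenuated(self, freq):
        fs = 1024.0
        t = np.arange(int(10 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = sp.sigma_bandpass(x, fs)
        core = slice(int(fs), int(-fs))
        assert np.std(y[core]) / np.std(x[core]) <= 0.1

    def test_white_noise_power_concentrated_in_band(self, rng):
        fs = 1024.0
        y = sp.sigma_bandpass(rng.standard_normal(int(60 * fs)), fs)
        psd = spectral.welch_psd(y, fs)
        total = np.trapezoid(psd.power, psd.freqs)
        sel = (psd.freqs >= 9) & (psd.freqs <= 17)
        in_band = np.trapezoid(psd.power[sel], psd.freqs[sel])
        assert in_band / total >= 0.90


class TestDetect:
    def _nrem_hyp(self, n_epochs):
        return Hypnogram(labels=("NREM",) * n_epochs)

    def test_zero_signal_no_events(self):
        hyp = self._nrem_hyp(5)
        events = sp.detect(np.zeros(5 * 4 * 1024), 1024.0, hyp)
        assert events == []

    def test_planted_burst_recovered_with_tight_bounds(self, rng):
        fs = 1024.0
        hyp = self._nrem_hyp(10)
        n = int(10 * 4 * fs)
        noise = sp.sigma_bandpass(rng.standard_normal(n) * 0.2, fs)
        burst = sd.spindle_burst(1.0, 13.0, 5 * np.std(noise) * 5, fs)
        x = noise.copy()
        start = int(10.0 * fs)
        x[start : start + len(burst)] += burst
        events = sp.detect(x, fs, hyp)
        assert len(events) == 1
        assert abs(events[0].start_s - 10.0) <= 0.1
        assert abs(events[0].end_s - 11.0) <= 0.1

    def test_burst_in_wake_epoch_ignored(self, rng):
        fs = 1024.0
        labels = ["NREM"] * 10
        labels[3] = "WAKE"
        hyp = Hypnogram(labels=tuple(labels))
        n = int(10 * 4 * fs)
        noise = sp.sigma_bandpass(rng.standard_normal(n) * 0.2, fs)
        burst = sd.spindle_burst(1.0, 13.0, 25 * np.std(noise), fs)
        x = noise.copy()
        start = int(13.0 * fs)  # inside the WAKE epoch [12, 16) s
        x[start : start + len(burst)] += burst
        events = sp.detect(x, fs, hyp)
        assert all(not (12.0 <= e.start_s < 16.0) for e in events)

    def test_no_nrem_raises(self):
        hyp = Hypnogram(labels=("WAKE",) * 4)
        with pytest.raises(ValueError, match="baseline undefined"):
            sp.detect(np.zeros(4 * 4 * 1024), 1024.0, hyp)


class TestEventMetrics:
    def test_sinusoid_amplitude_is_twice_peak(self):
        fs = 1024.0
        t = np.arange(int(8 * fs)) / fs
        x = 3.0 * np.sin(2 * np.pi * 13.0 * t)
        ev = sp.SpindleEvent("ch00", 2.0, 4.0)
        (out,) = sp.event_metrics([ev], x, fs)
        assert out.amplitude == pytest.approx(6.0, rel=0.01)

    def test_duration_from_bounds(self):
        ev = sp.SpindleEvent("ch00", 10.0, 11.2)
        assert ev.duration == pytest.approx(1.2)

    def test_scaling_homogeneity(self, rng):
        fs = 1024.0
        x = sp.sigma_bandpass(rng.standard_normal(int(8 * fs)), fs)
        ev = sp.SpindleEvent("ch00", 2.0, 3.0)
        (a,) = sp.event_metrics([ev], x, fs)
        (b,) = sp.event_metrics([ev], 2.0 * x, fs)
        assert b.amplitude == pytest.approx(2 * a.amplitude, rel=1e-9)
        assert b.power == pytest.approx(4 * a.power, rel=1e-9)

    def test_empty_event_rejected(self):
        ev = sp.SpindleEvent("ch00", 1.0, 1.001)
        with pytest.raises(ValueError, match="empty"):
            sp.event_metrics([ev], np.zeros(100), 10.0)


class TestDensity:
    def test_exact_ratio(self):
        events = [sp.SpindleEvent("c", i, i + 0.5) for i in range(12)]
        assert sp.density(events, 60.0) == 12 / 60.0

    def test_zero_events(self):
        assert sp.density([], 60.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sp.density([], 0.0)

    def test_simulator_rate_recovered(self):
        # oracle: planted count is Poisson(rate * NREM s); the recovered
        # density stays within 3 Poisson SDs of the configured rate
        rate = 0.1
        cfg = sd.SimConfig(
            n_channels=1, fs=1024.0, duration=900.0, spindle_rate=rate,
            spindle_amp_snr=5.0, spike_rate=0.0, seed=21,
        )
        rec, truth = sd.simulate_recording(cfg)
        events, _ = sp.detect_channel(
            rec.samples[0], cfg.fs, truth.hypnogram, "ch00"
        )
        nrem_s = truth.hypnogram.stage_seconds("NREM")
        d = sp.density(events, nrem_s)
        tol = 3 * np.sqrt(rate / nrem_s)  # 3 SD of a Poisson rate estimate
        assert abs(d - rate) <= tol


class TestEndToEnd:
    def test_recovery_and_amplitude(self):
        cfg = sd.SimConfig(
            n_channels=1, fs=1024.0, duration=600.0, spindle_rate=0.08,
            spindle_amp_snr=4.0, seed=13,
        )
        rec, truth = sd.simulate_recording(cfg)
        events, sig = sp.detect_channel(
            rec.samples[0], cfg.fs, truth.hypnogram, "ch00"
        )
        det = [(e.start_s, e.end_s) for e in events]
        planted = [(s, e) for c, s, e, a in truth.spindle_events]
        tp, fp, fn = sp.match_events(det, planted)
        assert tp / max(tp + fp, 1) >= 0.9
        assert tp / max(tp + fn, 1) >= 0.9

    def test_detector_idempotent_under_second_despike(self, rng):
        cfg = sd.SimConfig(
            n_channels=1, fs=1024.0, duration=240.0, spindle_rate=0.1, seed=3
        )
        rec, truth = sd.simulate_recording(cfg)
        x = sp.despike(rec.samples[0], cfg.fs)
        x2 = sp.despike(x, cfg.fs)
        e1 = sp.detect(
            sp.sigma_bandpass(sp.detrend_hp(x, cfg.fs), cfg.fs),
            cfg.fs, truth.hypnogram,
        )
        e2 = sp.detect(
            sp.sigma_bandpass(sp.detrend_hp(x2, cfg.fs), cfg.fs),
            cfg.fs, truth.hypnogram,
        )
        assert [(e.start_s, e.end_s) for e in e1] == [
            (e.start_s, e.end_s) for e in e2
        ]


class TestMatchEvents:
    def test_exact_match(self):
        tp, fp, fn = sp.match_events([(1.0, 2.0)], [(1.0, 2.0)])
        assert (tp, fp, fn) == (1, 0, 0)

    def test_insufficient_overlap(self):
        tp, fp, fn = sp.match_events([(1.0, 2.0)], [(1.9, 3.0)])
        assert (tp, fp, fn) == (0, 1, 1)

    def test_each_planted_matched_once(self):
        tp, fp, fn = sp.match_events([(1.0, 2.0), (1.1, 2.1)], [(1.0, 2.0)])
        assert (tp, fp, fn) == (1, 1, 0)
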