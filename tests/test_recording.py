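"""Recording analysis: filters, rms envelope, PSD, SNR, evoked, PSTH."""

import numpy as np
import pytest

from neurelec.errors import InvalidParameterError
from neurelec.recording import (
    PsdResult,
    RecordingSegment,
    SpikeData,
    average_evoked,
    detect_spikes,
    epoch_average,
    filter_band,
    psd,
    psth,
    sliding_rms,
    snr_spectrum,
)
from neurelec.synth import GeneratorConfig, gen_neural_recording

FS = 20000.0


def sine_segment(freq, amp=10.0, duration=2.0, fs=FS, offset=0.0):
    t = np.arange(int(duration * fs)) / fs
    return RecordingSegment(fs, offset + amp * np.sin(2 * np.pi * freq * t))


class TestFilterBand:
    def test_dc_removed_by_lfp_mode(self):
        seg = RecordingSegment(FS, np.full(int(FS), 3.0))
        out = filter_band(seg, "lfp")
        assert np.max(np.abs(out.data)) < 1e-6

    def test_mua_passband_and_stopband(self):
        inb = filter_band(sine_segment(1000.0), "mua")
        mid = slice(5000, -5000)
        assert np.std(inb.data[0, mid]) == pytest.approx(10 / np.sqrt(2), rel=0.02)
        low = filter_band(sine_segment(5.0), "mua")
        # > 40 dB attenuation of a 5 Hz tone
        assert np.std(low.data[0, mid]) < 0.01 * 10 / np.sqrt(2)

    def test_notch_suppresses_50hz(self):
        seg = sine_segment(50.0, duration=10.0)
        out = filter_band(seg, "notch")
        mid = slice(int(3 * FS), int(7 * FS))
        assert np.std(out.data[0, mid]) < 0.01 * np.std(seg.data[0, mid])

    def test_sua_band_limits(self):
        inb = filter_band(sine_segment(2000.0), "sua")
        mid = slice(5000, -5000)
        assert np.std(inb.data[0, mid]) == pytest.approx(10 / np.sqrt(2), rel=0.05)
        out = filter_band(sine_segment(100.0), "sua")
        assert np.std(out.data[0, mid]) < 0.05

    def test_lfp_idempotent_in_passband(self):
        seg = sine_segment(40.0, duration=4.0)
        once = filter_band(seg, "lfp")
        twice = filter_band(once, "lfp")
        mid = slice(int(FS), -int(FS))
        ratio = np.std(twice.data[0, mid]) / np.std(once.data[0, mid])
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_edge_above_nyquist_rejected(self):
        seg = sine_segment(100.0, fs=1000.0)
        with pytest.raises(InvalidParameterError):
            filter_band(seg, "sua")

    def test_lfp_downsample(self):
        seg = sine_segment(40.0)
        out = filter_band(seg, "lfp", downsample_to=1000.0)
        assert out.sampling_rate == 1000.0
        assert out.n_samples == seg.n_samples / 20


class TestSlidingRms:
    def test_zero_input(self):
        seg = RecordingSegment(FS, np.zeros(1000))
        assert not np.any(sliding_rms(seg))

    def test_sine_envelope(self):
        seg = sine_segment(1000.0, amp=4.0)
        env = sliding_rms(seg, window=0.020)
        mid = env[0, 1000:-1000]
        assert np.allclose(mid, 4.0 / np.sqrt(2), rtol=0.01)

    def test_white_noise_envelope_mean(self):
        seg, _ = gen_neural_recording(1, 2000.0, 60.0, GeneratorConfig(seed=3),
                                      noise_rms=2.5)
        env = sliding_rms(seg, window=0.020)
        assert np.mean(env) == pytest.approx(2.5, rel=0.05)

    def test_window_longer_than_trace_rejected(self):
        seg = RecordingSegment(FS, np.zeros(10))
        with pytest.raises(InvalidParameterError):
            sliding_rms(seg, window=1.0)


class TestPsd:
    def test_parseval_on_white_noise(self):
        seg, _ = gen_neural_recording(1, 2000.0, 60.0, GeneratorConfig(seed=4),
                                      noise_rms=2.5)
        res = psd(seg)
        total = np.trapezoid(res.psd[0], res.frequencies)
        assert np.sqrt(total) == pytest.approx(2.5, rel=0.05)

    def test_sine_dominant_bin(self):
        seg = sine_segment(440.0, duration=60.0, fs=2000.0)
        res = psd(seg)
        assert res.frequencies[np.argmax(res.psd[0])] == pytest.approx(440.0, abs=0.5)

    def test_deterministic(self):
        seg, _ = gen_neural_recording(1, 2000.0, 60.0, GeneratorConfig(seed=4),
                                      noise_rms=2.5)
        a = psd(seg)
        b = psd(seg)
        assert np.array_equal(a.psd, b.psd)

    def test_short_segment_rejected(self):
        seg = sine_segment(10.0, duration=2.0, fs=2000.0)
        with pytest.raises(InvalidParameterError, match="60"):
            psd(seg)


class TestSnrSpectrum:
    @staticmethod
    def flat_psd(level=1.0):
        f = np.linspace(1.0, 1100.0, 1100)
        return PsdResult(f, np.full((1, f.size), level))

    def test_identity_is_zero_db(self):
        s = snr_spectrum(self.flat_psd(), self.flat_psd())
        assert np.allclose(s.snr_db, 0.0)
        assert s.frequencies.size == 20
        assert s.frequencies[0] == pytest.approx(10.0)
        assert s.frequencies[-1] == pytest.approx(1000.0)

    def test_e_squared_power_is_20_db_natural(self):
        # amplitude ratio e: 20 * ln(e) = 20 dB under the natural convention
        s = snr_spectrum(self.flat_psd(np.e ** 2), self.flat_psd())
        assert np.allclose(s.snr_db, 20.0)

    def test_hundredfold_power_is_20_db_decadic(self):
        s = snr_spectrum(self.flat_psd(100.0), self.flat_psd(), convention="decadic")
        assert np.allclose(s.snr_db, 20.0)

    def test_antisymmetric_under_swap(self):
        a = self.flat_psd(4.0)
        b = self.flat_psd(1.0)
        fwd = snr_spectrum(a, b)
        rev = snr_spectrum(b, a)
        assert np.allclose(fwd.snr_db, -rev.snr_db)

    def test_nonpositive_pm_rejected(self):
        bad = self.flat_psd(0.0)
        with pytest.raises(InvalidParameterError):
            snr_spectrum(self.flat_psd(), bad)

    def test_insufficient_band_rejected(self):
        f = np.linspace(1.0, 500.0, 500)
        p = PsdResult(f, np.ones((1, f.size)))
        with pytest.raises(InvalidParameterError):
            snr_spectrum(p, p)


class TestEvoked:
    def test_single_noise_free_trial_equals_template(self, cfg0):
        spec = [dict(amplitude_uv=-50.0, latency_s=0.04, width_s=0.008)]
        seg, gt = gen_neural_recording(1, 2000.0, 2.0, cfg0, evoked_spec=spec,
                                       noise_rms=0.0, event_times=[1.0])
        times, avg, n = epoch_average(seg, [1.0])
        assert n == 1
        tpl = gt["evoked_template"]
        n_pre = int(round(0.020 * 2000))
        assert np.allclose(avg[n_pre:n_pre + tpl.size], tpl)

    def test_snr_ratio_recovers_construction(self):
        # template N1 -50 uV over ~5 uV single-trial noise, 100 trials
        cfg = GeneratorConfig(seed=8)
        events = np.arange(0.5, 50.5, 0.5)
        spec = [dict(amplitude_uv=-50.0, latency_s=0.04, width_s=0.008)]
        seg, _ = gen_neural_recording(1, 2000.0, 51.0, cfg, evoked_spec=spec,
                                      noise_rms=5.0, event_times=events)
        ev = average_evoked(seg)
        assert ev.n_trials == 100
        assert ev.n1_amplitude == pytest.approx(-50.0, rel=0.05)
        assert ev.n1_latency == pytest.approx(40.0, abs=5.0)
        expected_ratio = abs(ev.n1_amplitude) / ev.baseline_sd
        assert ev.aep_snr_ratio == pytest.approx(expected_ratio)
        assert ev.aep_snr_db == pytest.approx(20 * np.log(expected_ratio))

    def test_baseline_sd_shrinks_with_sqrt_n(self):
        cfg = GeneratorConfig(seed=12)
        events = np.arange(0.5, 50.5, 0.5)
        seg, _ = gen_neural_recording(1, 2000.0, 51.0, cfg,
                                      evoked_spec=[dict(amplitude_uv=-50.0,
                                                        latency_s=0.04,
                                                        width_s=0.008)],
                                      noise_rms=5.0, event_times=events)
        sds = [average_evoked(seg, events=events[:n]).baseline_sd
               for n in (1, 4, 16, 64)]
        slope = np.polyfit(np.log([1, 4, 16, 64]), np.log(sds), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_zero_baseline_sd_rejected(self, cfg0):
        seg, _ = gen_neural_recording(1, 2000.0, 2.0, cfg0,
                                      evoked_spec=[dict(amplitude_uv=-50.0,
                                                        latency_s=0.04,
                                                        width_s=0.008)],
                                      noise_rms=0.0, event_times=[1.0])
        with pytest.raises(InvalidParameterError, match="baseline"):
            average_evoked(seg, events=[1.0])


class TestPsth:
    def test_no_spikes_zero_histogram(self):
        res = psth(SpikeData("u", []), [1.0, 2.0])
        assert not np.any(res.counts)

    def test_spike_at_event_lands_in_zero_bin(self):
        events = [1.0, 2.0, 3.0]
        res = psth(SpikeData("u", events), events, bin_width=0.01)
        zero_bin = np.searchsorted(res.bin_edges, 0.0, side="right") - 1
        assert res.counts[zero_bin] == 3
        assert res.counts.sum() == 3

    def test_poisson_total_count(self):
        rng = np.random.default_rng(17)
        rate, T = 20.0, 0.5
        events = np.arange(0.0, 100.0, 1.0)
        spikes = np.sort(rng.uniform(0, 100, rng.poisson(rate * 100)))
        res = psth(SpikeData("u", spikes), events, bin_width=0.05, window=(0.0, T))
        expected = events.size * rate * T
        assert abs(res.counts.sum() - expected) < 3 * np.sqrt(expected)

    def test_empty_events_rejected(self):
        with pytest.raises(InvalidParameterError):
            psth(SpikeData("u", [1.0]), [])


class TestDetectSpikes:
    def test_recovers_synthetic_spike_times(self):
        cfg = GeneratorConfig(seed=21)
        seg, gt = gen_neural_recording(
            1, 20000.0, 10.0, cfg, noise_rms=3.0,
            spike_spec=[dict(rate_hz=4.0, amplitude_uv=-120.0)])
        detected = detect_spikes(seg)
        truth = gt["spike_times"]["u0"]
        # most true spikes matched within 1 ms
        matched = sum(np.min(np.abs(detected - t)) < 1e-3 for t in truth
                      if detected.size)
        assert matched >= 0.8 * truth.size
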