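"""Stage-1 chain: notch, segmentation, de-jitter, excision, reconstruction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gerscore.errors import (
    AllSegmentsExcisedError,
    ConfigurationError,
    TooShortError,
)
from gerscore.signal_io import Recording
from gerscore.scoring import ScoreConfig, mean_amplitude, spectrogram
from gerscore.spectral_qc import (
    QcConfig,
    dejitter,
    direct_band_mean,
    excise_artifacts,
    notch_filter,
    reconstruct_and_decimate,
    run_qc,
    segment_fft,
)

from conftest import dft_amplitude, fit_sinusoid_amplitude, tone

CFG = QcConfig()


class TestNotchFilter:
    def test_60hz_tone_attenuated_40db(self):
        rec = tone(60.0, 100.0, 2000, 200.0, phase=0.7)
        out = notch_filter(rec, CFG)
        # 10 s at 200 Hz: 600 integer cycles; direct-DFT oracle at 60 Hz
        assert dft_amplitude(out.samples, 60.0, 200.0) <= 1.0
        assert dft_amplitude(rec.samples, 60.0, 200.0) == pytest.approx(100.0, rel=1e-9)

    def test_passband_5hz_within_1pct(self):
        out = notch_filter(tone(5.0, 100.0, 2000, 200.0), CFG)
        assert 99.0 <= dft_amplitude(out.samples, 5.0, 200.0) <= 101.0

    def test_zero_signal_stays_zero(self):
        out = notch_filter(Recording(samples=np.zeros(1000), fs=200.0), CFG)
        assert np.all(out.samples == 0.0)

    def test_fs_too_low_for_notch(self):
        with pytest.raises(ConfigurationError):
            notch_filter(Recording(samples=np.zeros(100), fs=100.0), CFG)


class TestSegmentFft:
    def test_bin_centered_tone_recovers_amplitude(self):
        k, fs, n = 51, 200.0, 1024
        f = k * fs / n
        specs = segment_fft(tone(f, 7.5, n, fs), CFG)
        assert len(specs) == 1
        amp = specs[0].amplitudes
        # brute-force DFT oracle: all energy in bin k
        assert amp[k] == pytest.approx(7.5, rel=1e-9)
        others = np.delete(amp, k)
        assert np.max(others) < 1e-9

    def test_constant_signal_detrended_to_zero(self):
        specs = segment_fft(Recording(samples=np.full(1024, 42.0), fs=200.0), CFG)
        assert np.max(specs[0].amplitudes) < 1e-9

    def test_trailing_remainder_dropped(self):
        specs = segment_fft(Recording(samples=np.zeros(2049), fs=200.0), CFG)
        assert len(specs) == 2

    def test_too_short_rejected(self):
        with pytest.raises(TooShortError):
            segment_fft(Recording(samples=np.zeros(1023), fs=200.0), CFG)

    def test_bin_count_and_freq_span(self):
        specs = segment_fft(Recording(samples=np.zeros(1024), fs=200.0), CFG)
        assert len(specs[0].freqs) == 1024 // 2 + 1
        assert specs[0].freqs[0] == 0.0 and specs[0].freqs[-1] == 100.0


class TestDejitter:
    def test_floor_arithmetic(self):
        spec = segment_fft(Recording(samples=np.zeros(1024), fs=200.0), CFG)[0]
        spec.amplitudes = np.array([350.0, 150.0, 0.0] + [0.0] * 510)
        out = dejitter(spec, CFG)
        assert out.amplitudes[0] == 150.0  # 350 - 200
        assert out.amplitudes[1] == 0.0    # clamped at zero
        assert out.amplitudes[2] == 0.0

    def test_phases_unchanged(self):
        spec = segment_fft(tone(5.078125, 300.0, 1024, 200.0), CFG)[0]
        out = dejitter(spec, CFG)
        np.testing.assert_array_equal(out.phases, spec.phases)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=1, max_size=20))
    def test_energy_never_increases(self, amps):
        spec = segment_fft(Recording(samples=np.zeros(1024), fs=200.0), CFG)[0]
        a = np.zeros(513)
        a[: len(amps)] = amps
        spec.amplitudes = a
        out = dejitter(spec, CFG)
        assert np.sum(out.amplitudes**2) <= np.sum(a**2) + 1e-9
        assert np.all(out.amplitudes >= 0)


class TestExcision:
    def _spec_with(self, freq_hz, amp):
        spec = segment_fft(Recording(samples=np.zeros(1024), fs=200.0), CFG)[0]
        k = int(round(freq_hz * 1024 / 200))
        spec.amplitudes = np.zeros(513)
        spec.amplitudes[k] = amp
        return spec

    def test_hot_bin_above_60hz_excises(self):
        out = excise_artifacts([self._spec_with(65.0, 250.0)], CFG)
        assert out[0].excised and "65" in out[0].excision_reason

    def test_boundary_amplitude_retained(self):
        # strict inequality: exactly 200 µV does not excise
        out = excise_artifacts([self._spec_with(65.0, 200.0)], CFG)
        assert not out[0].excised

    def test_low_frequency_energy_never_excises(self):
        out = excise_artifacts([self._spec_with(30.0, 10000.0)], CFG)
        assert not out[0].excised

    def test_order_independent(self, rng):
        specs = [self._spec_with(61.0 + i, 150.0 + 20 * i) for i in range(6)]
        flags = [s.excised for s in excise_artifacts(specs, CFG)]
        perm = rng.permutation(6)
        flags_perm = [s.excised for s in excise_artifacts([specs[i] for i in perm], CFG)]
        assert flags_perm == [flags[i] for i in perm]


class TestReconstruction:
    def test_floored_tone_amplitude(self):
        # one segment, bin-centered ~5 Hz tone at 300 µV; floor 200 -> ~100 µV out
        f = 26 * 200.0 / 1024
        specs = segment_fft(tone(f, 300.0, 1024, 200.0), CFG)
        specs = excise_artifacts([dejitter(s, CFG) for s in specs], CFG)
        clean = reconstruct_and_decimate(specs, CFG)
        assert clean.fs == 60.0
        interior = clean.samples[30:-30]
        amp = fit_sinusoid_amplitude(interior, f, 60.0)
        assert amp == pytest.approx(100.0, rel=0.02)

    def test_all_zero_in_all_zero_out(self):
        specs = segment_fft(Recording(samples=np.zeros(2048), fs=200.0), CFG)
        clean = reconstruct_and_decimate(excise_artifacts(specs, CFG), CFG)
        assert np.allclose(clean.samples, 0.0)

    def test_excised_segment_shortens_output(self):
        specs = segment_fft(Recording(samples=np.zeros(3 * 1024), fs=200.0), CFG)
        specs[1].excised = True
        clean = reconstruct_and_decimate(specs, CFG)
        expect = 2 * (1024 / 200.0) * 60.0
        assert abs(len(clean.samples) - expect) <= 1

    def test_all_excised_is_an_error(self):
        specs = segment_fft(Recording(samples=np.zeros(1024), fs=200.0), CFG)
        specs[0].excised = True
        with pytest.raises(AllSegmentsExcisedError):
            reconstruct_and_decimate(specs, CFG)

    def test_no_energy_above_30hz_after_decimation(self, rng):
        # broadband input: anti-alias contract on the 60 Hz output
        rec = Recording(samples=1000 * rng.standard_normal(8 * 1024), fs=200.0)
        specs = excise_artifacts(segment_fft(rec, QcConfig(dejitter_floor=0.0)), CFG)
        clean = reconstruct_and_decimate(specs, CFG)
        spec = np.abs(np.fft.rfft(clean.samples)) ** 2
        freqs = np.fft.rfftfreq(len(clean.samples), 1 / 60.0)
        hi = spec[freqs > 30.0].sum()
        assert hi <= 0.01 * spec.sum()


class TestPipelineAgreement:
    def test_floored_multitone_recovers_input_minus_floor(self):
        # occupied bins (all <25 Hz, stage-1 bin-centered, >400 µV) come
        # through the full reconstruction at input - 200 µV within 2%
        fs, n = 200.0, 1024
        comps = [(30, 800.0), (60, 500.0), (90, 1200.0)]  # k multiples of 3
        t = np.arange(8 * n) / fs
        x = sum(a * np.sin(2 * np.pi * (k * fs / n) * t + 0.3 * k) for k, a in comps)
        specs = [dejitter(s, CFG) for s in segment_fft(Recording(samples=x, fs=fs), CFG)]
        clean = reconstruct_and_decimate(excise_artifacts(specs, CFG), CFG)
        for k, a in comps:
            f = k * fs / n
            got = fit_sinusoid_amplitude(clean.samples[40:-40], f, 60.0)
            assert got == pytest.approx(a - 200.0, rel=0.02)

    def test_direct_and_reconstruction_scores_agree(self):
        fs, n = 200.0, 1024
        t = np.arange(20 * n) / fs
        x = sum(
            a * np.sin(2 * np.pi * (k * fs / n) * t)
            for k, a in [(18, 600.0), (45, 900.0), (120, 700.0)]
        )
        qc = run_qc(Recording(samples=x, fs=fs), CFG)
        recon_score = mean_amplitude(spectrogram(qc.clean, ScoreConfig()))
        direct_score = direct_band_mean(qc.segments, CFG)
        assert recon_score == pytest.approx(direct_score, rel=0.05)
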