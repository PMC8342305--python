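"""Stage-2 scoring: spectrogram, mean amplitude, positivity, episodes, patterns."""
import numpy as np
import pytest

from gerscore.errors import TooShortError, ValidationError
from gerscore.signal_io import Recording
from gerscore.scoring import (
    ScoreConfig,
    Spectrogram,
    classify,
    episode_features,
    mean_amplitude,
    pattern_label,
    score_recording,
    spectrogram,
)
from gerscore.spectral_qc import QcConfig

from conftest import tone

CFG = ScoreConfig()


def make_spectrogram(column_means, n_bins=257):
    """Spectrogram whose per-column band mean equals the requested values."""
    cols = np.tile(np.asarray(column_means, dtype=float), (n_bins, 1))
    T = 512 / 60.0
    return Spectrogram(
        times=(np.arange(len(column_means)) + 0.5) * T,
        freqs=np.linspace(0, 30, n_bins),
        amplitudes=cols,
        column_duration=T,
    )


class TestSpectrogram:
    def test_bin_centered_tone_in_both_columns(self):
        f = 43 * 60.0 / 512  # ~5.04 Hz, bin-centered
        spec = spectrogram(tone(f, 2.0, 1024, 60.0), CFG)
        assert spec.amplitudes.shape == (257, 2)
        # brute-force DFT oracle: amplitude 2 µV in bin 43 of each column
        assert spec.amplitudes[43, 0] == pytest.approx(2.0, rel=1e-9)
        assert spec.amplitudes[43, 1] == pytest.approx(2.0, rel=1e-9)
        assert np.max(np.delete(spec.amplitudes, 43, axis=0)) < 1e-9

    def test_zero_signal_all_zero(self):
        spec = spectrogram(Recording(samples=np.zeros(1024), fs=60.0), CFG)
        assert np.max(spec.amplitudes) < 1e-12

    def test_partial_trailing_column_dropped(self):
        spec = spectrogram(Recording(samples=np.zeros(600), fs=60.0), CFG)
        assert spec.n_columns == 1

    def test_too_short_names_minimum(self):
        with pytest.raises(TooShortError, match="512"):
            spectrogram(Recording(samples=np.zeros(100), fs=60.0), CFG)

    def test_freqs_span_0_to_30(self):
        spec = spectrogram(Recording(samples=np.zeros(512), fs=60.0), CFG)
        assert spec.freqs[0] == 0.0 and spec.freqs[-1] == 30.0


class TestMeanAmplitude:
    def test_constant_cells(self):
        assert mean_amplitude(make_spectrogram([1.5, 1.5]), CFG) == pytest.approx(1.5)

    def test_half_zero_half_two(self):
        assert mean_amplitude(make_spectrogram([0, 0, 2, 2]), CFG) == pytest.approx(1.0)

    def test_single_occupied_bin_diluted_over_band(self):
        spec = make_spectrogram([0.0])
        spec.amplitudes[:, 0] = 0.0
        spec.amplitudes[43, 0] = 2.0
        assert mean_amplitude(spec, CFG) == pytest.approx(2.0 / 257)


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected",
        [(1.0, True), (0.999, False), (0.0, False), (5.2, True)],
    )
    def test_inclusive_cutoff(self, score, expected):
        assert classify(score, CFG) is expected

    def test_negative_score_rejected(self):
        with pytest.raises(ValidationError):
            classify(-0.1, CFG)


class TestEpisodeFeatures:
    def test_single_run(self):
        f = episode_features(make_spectrogram([0.2, 1.5, 1.5, 0.2]), CFG)
        assert f["n_episodes"] == 1
        assert f["longest_episode"] == pytest.approx(2 * 512 / 60.0)
        assert f["pct_time_positive"] == pytest.approx(50.0)
        assert f["max_column_amplitude"] == pytest.approx(1.5)

    def test_all_below_cutoff(self):
        f = episode_features(make_spectrogram([0.1, 0.5, 0.9]), CFG)
        assert f["n_episodes"] == 0 and f["pct_time_positive"] == 0.0

    def test_split_runs(self):
        f = episode_features(make_spectrogram([2, 0.5, 2]), CFG)
        assert f["n_episodes"] == 2

    def test_excision_gap_breaks_run(self):
        spec = make_spectrogram([2, 2, 2, 2])
        T = 512 / 60.0
        whole = episode_features(spec, CFG)
        broken = episode_features(spec, CFG, gap_times_s=[1.5 * T])
        assert whole["n_episodes"] == 1
        assert broken["n_episodes"] == 2
        assert broken["longest_episode"] == pytest.approx(2 * T)


class TestPatternLabel:
    def _clean(self, env_fn, duration_s=240.0, fs=60.0, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(int(duration_s * fs)) / fs
        x = env_fn(t) * rng.standard_normal(len(t))
        return Recording(samples=x, fs=fs)

    def test_zero_signal_negative(self):
        clean = Recording(samples=np.zeros(2048), fs=60.0)
        feats = episode_features(spectrogram(clean, CFG), CFG)
        assert pattern_label(feats, clean, CFG) == "negative"

    def test_long_uninterrupted_episode_continuous(self):
        n_cols = 180  # 180 * 8.53 s = 25.6 min, all active
        feats = episode_features(make_spectrogram([2.0] * n_cols), CFG)
        clean = Recording(samples=np.ones(10), fs=60.0)
        assert pattern_label(feats, clean, CFG) == "continuous"

    def test_4_per_minute_bursts_rhythmic(self):
        # envelope autocorrelation oracle: bursts every 15 s -> 15 s dominant lag
        clean = self._clean(lambda t: 5.0 * (np.sin(2 * np.pi * t / 15.0) > 0.5))
        feats = {"n_episodes": 3, "longest_episode": 30.0}
        assert pattern_label(feats, clean, CFG) == "rhythmic"

    def test_aperiodic_bursts_intermittent(self):
        def env(t):
            out = np.zeros_like(t)
            for s in (10.0, 95.0, 150.0, 228.0):  # irregular spacing
                out += ((t >= s) & (t < s + 6.0)) * 5.0
            return out

        clean = self._clean(env)
        feats = {"n_episodes": 4, "longest_episode": 8.5}
        assert pattern_label(feats, clean, CFG) == "intermittent"


class TestScoreInvariances:
    FLOOR0 = QcConfig(dejitter_floor=0.0)

    def _score(self, x):
        rep = score_recording(Recording(samples=x, fs=200.0), self.FLOOR0, CFG)
        return rep.mean_amplitude

    def test_scale_equivariance(self, rng):
        x = 50.0 * rng.standard_normal(4 * 1024)
        assert self._score(3.0 * x) == pytest.approx(3.0 * self._score(x), rel=1e-6)

    def test_burst_never_decreases_score(self, rng):
        x = 20.0 * rng.standard_normal(4 * 1024)
        burst = np.zeros_like(x)
        t = np.arange(2048) / 200.0
        burst[1024 : 1024 + 2048] = 300.0 * np.sin(2 * np.pi * 5.0 * t)
        assert self._score(x + burst) >= self._score(x) - 1e-9

    def test_time_reversal_invariant_call(self, rng):
        x = 50.0 * rng.standard_normal(6 * 1024)
        t = np.arange(len(x)) / 200.0
        x = x + 400.0 * np.sin(2 * np.pi * 7.0 * t)
        fwd = score_recording(Recording(samples=x, fs=200.0), QcConfig(), CFG)
        rev = score_recording(Recording(samples=x[::-1].copy(), fs=200.0), QcConfig(), CFG)
        assert fwd.positive == rev.positive


class TestShortRecordingFlag:
    def test_under_30_min_flagged(self):
        rep = score_recording(tone(5.0, 50.0, 8 * 1024, 200.0), QcConfig(), CFG)
        assert rep.short_recording_flag
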