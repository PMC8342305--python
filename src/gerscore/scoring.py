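"""Stage-2 scoring of the cleaned 60 Hz signal.

A spectrogram is built from consecutive 512-sample windows (8.53 s
columns, single-sided amplitudes in µV over the focused 0-30 Hz band),
and the score is the arithmetic mean of every cell in the band across
the whole recording.  A mean of >= 1 µV over the recording is called
positive ("abnormal").  Episode features (% time positive, highest
column amplitude, longest episode, number of episodes) and a pattern
label — negative, intermittent, rhythmic (~4 events/min) or continuous
(>= 20 min uninterrupted) — are derived from per-column activity.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, TooShortError, ValidationError
from .signal_io import Recording
from .spectral_qc import QcConfig, QcResult, run_qc

__all__ = [
    "ScoreConfig",
    "Spectrogram",
    "AccelReport",
    "spectrogram",
    "mean_amplitude",
    "classify",
    "episode_features",
    "pattern_label",
    "score_recording",
]

PATTERNS = ("negative", "intermittent", "rhythmic", "continuous")


@dataclass(frozen=True)
class ScoreConfig:
    """Stage-2 parameters.

    ``positive_cutoff`` is the preliminary 1 µV "abnormal" threshold on the
    whole-recording mean amplitude (inclusive: >= 1 µV is positive).
    ``continuous_min_duration`` (20 min) separates the continuous pattern;
    ``rhythmic_rate_per_min`` (4/min, +/-50%) the rhythmic one.
    """

    spec_segment: int = 512          # samples per spectrogram column (at 60 Hz)
    focus_low: float = 0.0           # Hz
    focus_high: float = 30.0         # Hz
    positive_cutoff: float = 1.0     # µV, inclusive
    rhythmic_rate_per_min: float = 4.0
    rhythmic_tolerance: float = 0.5  # fractional tolerance on the rate
    rhythmic_min_autocorr: float = 0.2
    continuous_min_duration: float = 1200.0  # s
    min_valid_duration_s: float = 1800.0     # flag scores from less retained signal

    def __post_init__(self) -> None:
        if not (0 <= self.focus_low < self.focus_high):
            raise ConfigurationError("need 0 <= focus_low < focus_high")
        if not self.positive_cutoff > 0:
            raise ConfigurationError("positive_cutoff must be positive")

    def validate_for(self, fs: float) -> None:
        if self.focus_high > fs / 2:
            raise ConfigurationError(
                f"focus_high {self.focus_high} Hz exceeds Nyquist {fs / 2} Hz"
            )


@dataclass
class Spectrogram:
    """Amplitude spectrogram (freq x time) of the clean 60 Hz signal."""

    times: np.ndarray       # s, column centers
    freqs: np.ndarray       # Hz
    amplitudes: np.ndarray  # µV, shape (len(freqs), len(times))
    column_duration: float  # s

    @property
    def n_columns(self) -> int:
        return self.amplitudes.shape[1]


@dataclass
class AccelReport:
    """Full accelerometric scoring report for one recording."""

    subject_id: str
    mean_amplitude: float        # µV over the focused band, whole recording
    positive: bool               # mean_amplitude >= positive_cutoff
    pct_time_positive: float     # % of columns at/above cutoff
    max_column_amplitude: float  # µV, highest per-column band mean
    longest_episode: float       # s
    n_episodes: int
    pattern: str                 # negative | intermittent | rhythmic | continuous
    excised_fraction: float      # % of stage-1 segments excised
    retained_duration_s: float
    short_recording_flag: bool   # retained signal below min_valid_duration_s
    config_echo: dict


def spectrogram(clean: Recording, cfg: ScoreConfig = ScoreConfig()) -> Spectrogram:
    """Non-overlapping 512-sample spectrogram of the 60 Hz clean signal.

    Windows are rectangular with per-window mean removal and the same
    single-sided sinusoid-amplitude normalization as stage 1; the trailing
    remainder shorter than one window is dropped.
    """
    cfg.validate_for(clean.fs)
    n = cfg.spec_segment
    if len(clean.samples) < n:
        raise TooShortError(
            f"need at least {n} samples ({n / clean.fs:.2f} s) at "
            f"{clean.fs:g} Hz for one spectrogram column"
        )
    ncols = len(clean.samples) // n
    freqs = np.fft.rfftfreq(n, d=1.0 / clean.fs)
    amps = np.empty((len(freqs), ncols))
    for j in range(ncols):
        seg = clean.samples[j * n : (j + 1) * n]
        seg = seg - seg.mean()
        X = np.fft.rfft(seg)
        a = np.abs(X) * (2.0 / n)
        a[0] *= 0.5
        a[-1] *= 0.5
        amps[:, j] = a
    col_dur = n / clean.fs
    times = (np.arange(ncols) + 0.5) * col_dur
    return Spectrogram(times=times, freqs=freqs, amplitudes=amps, column_duration=col_dur)


def _band_mask(spec: Spectrogram, cfg: ScoreConfig) -> np.ndarray:
    return (spec.freqs >= cfg.focus_low) & (spec.freqs <= cfg.focus_high)


def mean_amplitude(spec: Spectrogram, cfg: ScoreConfig = ScoreConfig()) -> float:
    """Arithmetic mean of all focused-band cells across all columns (µV)."""
    if spec.n_columns == 0:
        raise ValidationError("empty spectrogram")
    return float(np.mean(spec.amplitudes[_band_mask(spec, cfg), :]))


def classify(score: float, cfg: ScoreConfig = ScoreConfig()) -> bool:
    """Positivity call: True iff score >= positive_cutoff (inclusive)."""
    if score < 0:
        raise ValidationError(f"score must be non-negative, got {score}")
    return bool(score >= cfg.positive_cutoff)


def column_means(spec: Spectrogram, cfg: ScoreConfig = ScoreConfig()) -> np.ndarray:
    """Per-column mean amplitude over the focused band (µV)."""
    return spec.amplitudes[_band_mask(spec, cfg), :].mean(axis=0)


def _runs(active: np.ndarray, break_after: set) -> List[tuple]:
    """Maximal runs of True, never spanning a forced break after index i."""
    runs = []
    start = None
    for i, a in enumerate(active):
        if a and start is None:
            start = i
        end_here = (not a) or (i in break_after) or (i == len(active) - 1)
        if start is not None and end_here:
            stop = i if a else i - 1
            if stop >= start:
                runs.append((start, stop))
            start = None
    return runs


def episode_features(
    spec: Spectrogram,
    cfg: ScoreConfig = ScoreConfig(),
    gap_times_s: Sequence[float] = (),
) -> dict:
    """Per-column activity and episode statistics.

    A column is active iff its focused-band mean is at/above the positivity
    cutoff; episodes are maximal runs of active columns.  Runs are broken at
    excision-gap positions (``gap_times_s``, in clean-signal time), so
    artifact gaps never extend an episode.
    """
    if spec.n_columns == 0:
        raise ValidationError("empty spectrogram")
    col = column_means(spec, cfg)
    active = col >= cfg.positive_cutoff
    T = spec.column_duration
    break_after = set()
    for g in gap_times_s:
        j = int(np.floor(g / T))
        if 0 <= j < len(col) - 1:
            break_after.add(j)
    runs = _runs(active, break_after)
    longest = max(((b - a + 1) for a, b in runs), default=0) * T
    return {
        "n_episodes": len(runs),
        "longest_episode": float(longest),
        "pct_time_positive": float(100.0 * active.sum() / len(active)),
        "max_column_amplitude": float(col.max()),
        "column_means": col,
        "active": active,
    }


def _rms_envelope(x: np.ndarray, fs: float, block_s: float = 1.0) -> np.ndarray:
    n = max(int(round(block_s * fs)), 1)
    nb = len(x) // n
    if nb == 0:
        return np.array([])
    blocks = x[: nb * n].reshape(nb, n)
    return np.sqrt(np.mean(blocks**2, axis=1))


def dominant_period_s(
    clean: Recording, lag_range_s: tuple = (3.0, 60.0), block_s: float = 1.0
) -> tuple:
    """Dominant periodicity of the 1 s RMS envelope, by autocorrelation.

    Returns ``(period_s, normalized_autocorrelation)``; (nan, 0) when the
    envelope is flat or too short.  The envelope — not the raw signal — is
    used because rhythmicity here means a slow on/off modulation of burst
    activity, not an oscillation at signal frequencies.
    """
    env = _rms_envelope(clean.samples, clean.fs, block_s)
    if len(env) < 2 * lag_range_s[0] / block_s + 2:
        return float("nan"), 0.0
    e = env - env.mean()
    denom = float(np.dot(e, e))
    if denom <= 0:
        return float("nan"), 0.0
    ac = np.correlate(e, e, mode="full")[len(e) - 1 :] / denom
    lo = max(int(np.ceil(lag_range_s[0] / block_s)), 1)
    hi = min(int(np.floor(lag_range_s[1] / block_s)), len(ac) - 1)
    if hi <= lo:
        return float("nan"), 0.0
    k = lo + int(np.argmax(ac[lo : hi + 1]))
    return k * block_s, float(ac[k])


def pattern_label(
    features: dict,
    clean: Recording,
    cfg: ScoreConfig = ScoreConfig(),
) -> str:
    """Classify the temporal pattern of accelerometric activity.

    negative: no active episode; continuous: an uninterrupted episode of at
    least ``continuous_min_duration``; rhythmic: the activity envelope has a
    dominant period within +/-``rhythmic_tolerance`` of the 4/min rate
    (detected on a 1 s RMS envelope — spectrogram columns are too coarse);
    otherwise intermittent.
    """
    if features["n_episodes"] == 0:
        return "negative"
    if features["longest_episode"] >= cfg.continuous_min_duration:
        return "continuous"
    target = 60.0 / cfg.rhythmic_rate_per_min
    lo = target * (1.0 - cfg.rhythmic_tolerance)
    hi = target * (1.0 + cfg.rhythmic_tolerance)
    period, strength = dominant_period_s(clean)
    if np.isfinite(period) and lo <= period <= hi and strength >= cfg.rhythmic_min_autocorr:
        return "rhythmic"
    return "intermittent"


def score_recording(
    rec: Recording,
    qc_cfg: QcConfig = QcConfig(),
    cfg: ScoreConfig = ScoreConfig(),
    qc_result: Optional[QcResult] = None,
) -> AccelReport:
    """Run the full pipeline on a raw 200 Hz recording and build the report."""
    qc = qc_result if qc_result is not None else run_qc(rec, qc_cfg)
    spec = spectrogram(qc.clean, cfg)
    score = mean_amplitude(spec, cfg)
    feats = episode_features(spec, cfg, qc.gap_times_s)
    pat = pattern_label(feats, qc.clean, cfg)
    retained = qc.retained_duration_s
    return AccelReport(
        subject_id=rec.subject_id,
        mean_amplitude=score,
        positive=classify(score, cfg),
        pct_time_positive=feats["pct_time_positive"],
        max_column_amplitude=feats["max_column_amplitude"],
        longest_episode=feats["longest_episode"],
        n_episodes=feats["n_episodes"],
        pattern=pat,
        excised_fraction=100.0 * qc.excised_fraction,
        retained_duration_s=retained,
        short_recording_flag=retained < cfg.min_valid_duration_s,
        config_echo={
            "positive_cutoff_uV": cfg.positive_cutoff,
            "focus_band_hz": [cfg.focus_low, cfg.focus_high],
            "spec_segment": cfg.spec_segment,
            "dejitter_floor_uV": qc.config.dejitter_floor,
            "artifact_threshold_uV": qc.config.artifact_threshold,
            "resample_fs_hz": qc.config.resample_fs,
        },
    )
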