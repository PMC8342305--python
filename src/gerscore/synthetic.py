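"""Seeded generator of paired accelerometer + pH recordings with ground truth.

The accelerometer model emulates the signal structure the pipeline
assumes: Gaussian baseline sensor noise, 60 Hz mains contamination,
low-frequency (0.5-10 Hz) band-limited oscillation bursts at reflux
events (optionally as a rhythmic ~4/min burst train), and broadband
61-100 Hz transients standing in for motion/handling artifact.  The
paired pH trace sits near a milk-feed baseline of ~6.5 with slow drift;
acid events dip exponentially below pH 4 while non-acid events — the
majority in preterm infants — never cross the acid threshold by
construction.

Event strength is specified as the target stage-1 per-bin spectral
amplitude (µV), so the interaction with the 200 µV de-jitter floor is
explicit: the default 600 µV events survive flooring at ~400 µV per
occupied bin, while events specified below the floor vanish and serve
as negative controls.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal as sps

from .errors import GenerationError
from .signal_io import PhRecording, Recording

__all__ = ["SimConfig", "GroundTruth", "simulate_pair", "cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the standard study conditions.

    One 30 s reflux event per 10 min recording corresponds to a 6/h event
    rate; ``event_amp_uv`` is the target per-bin stage-1 spectral amplitude
    (600 µV floors to ~400 µV after de-jitter).  ``acid_fraction`` defaults
    to 0.3, matching the predominance of non-acid reflux in preterm infants.
    """

    seed: int = 0
    duration_s: float = 600.0
    fs: float = 200.0
    baseline_noise_uv: float = 50.0    # µV RMS white sensor noise
    mains_amp_uv: float = 300.0        # µV, 60 Hz sinusoid
    n_reflux_events: int = 1           # 6/h at the default duration
    event_amp_uv: float = 600.0        # target stage-1 per-bin amplitude, µV
    event_band: Tuple[float, float] = (0.5, 10.0)  # Hz
    event_duration_s: float = 30.0
    rhythmic: bool = False             # modulate events as a 4/min burst train
    rhythmic_rate_per_min: float = 4.0
    n_artifacts: int = 1
    artifact_amp_uv: float = 600.0     # target per-bin amplitude in 61-100 Hz
    artifact_duration_s: float = 5.12  # one stage-1 segment at defaults
    artifact_band: Tuple[float, float] = (61.0, 100.0)
    acid_fraction: float = 0.3         # probability a reflux event is acid
    ph_fs: float = 1.0
    ph_baseline: float = 6.5
    ph_drop_depth: float = 3.5         # acid events dip to baseline - depth
    ph_recovery_s: float = 60.0
    fft_segment: int = 1024            # stage-1 window, sets the bin width

    def __post_init__(self) -> None:
        if not 0.0 <= self.acid_fraction <= 1.0:
            raise GenerationError("acid_fraction must be in [0, 1]")
        lo, hi = self.event_band
        if not 0 < lo < hi < self.fs / 2:
            raise GenerationError("event_band must lie within (0, fs/2)")
        for name in ("baseline_noise_uv", "mains_amp_uv", "event_amp_uv", "artifact_amp_uv"):
            if getattr(self, name) < 0:
                raise GenerationError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """What the generator injected, for end-to-end validation."""

    event_intervals: List[Tuple[float, float, bool]]  # (start_s, end_s, is_acid)
    artifact_intervals: List[Tuple[float, float]]
    expected_positive: bool


def _band_noise_sigma(amp_per_bin: float, band: Tuple[float, float], fs: float, nfft: int) -> float:
    """RMS making the expected stage-1 per-bin amplitude equal ``amp_per_bin``.

    White noise of RMS sigma confined to a band occupying M bins has
    E[amplitude^2] = 2 sigma^2 / M per bin; inverting gives the required
    sigma (the Rayleigh mean amplitude is ~0.89x the RMS bin amplitude).
    """
    df = fs / nfft
    m = max(int(np.floor(band[1] / df)) - int(np.ceil(band[0] / df)) + 1, 1)
    return amp_per_bin * np.sqrt(m / 2.0)


def _band_limited_burst(
    rng: np.random.Generator,
    n: int,
    band: Tuple[float, float],
    sigma: float,
    fs: float,
    taper_frac: float = 0.1,
) -> np.ndarray:
    """Tapered band-limited Gaussian noise burst with RMS ``sigma``."""
    white = rng.standard_normal(n + 2 * int(fs))  # pad to flush filter edges
    if band[1] >= fs / 2:  # band reaches Nyquist: highpass only
        sos = sps.butter(4, band[0], btype="highpass", fs=fs, output="sos")
    else:
        sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    shaped = sps.sosfiltfilt(sos, white)[int(fs) : int(fs) + n]
    rms = np.sqrt(np.mean(shaped**2))
    if rms > 0:
        shaped = shaped * (sigma / rms)
    return shaped * sps.windows.tukey(n, alpha=2 * taper_frac)


def _place_intervals(
    rng: np.random.Generator,
    n_events: int,
    duration: float,
    event_dur: float,
    forbidden: List[Tuple[float, float]],
    label: str,
    max_tries: int = 200,
) -> List[Tuple[float, float]]:
    """Place non-overlapping intervals uniformly, avoiding forbidden spans."""
    placed: List[Tuple[float, float]] = []
    for _ in range(n_events):
        ok = False
        for _ in range(max_tries):
            start = rng.uniform(0.0, duration - event_dur)
            cand = (start, start + event_dur)
            clashes = any(
                cand[0] < e and s < cand[1] for s, e in placed + forbidden
            )
            if not clashes:
                placed.append(cand)
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"cannot place {n_events} non-overlapping {label} intervals of "
                f"{event_dur:g} s in {duration:g} s"
            )
    return sorted(placed)


def _ph_trace(
    rng: np.random.Generator, cfg: SimConfig, events: List[Tuple[float, float, bool]]
) -> PhRecording:
    n = int(round(cfg.duration_s * cfg.ph_fs))
    t = np.arange(n) / cfg.ph_fs
    drift = 0.3 * np.sin(2 * np.pi * t / max(cfg.duration_s, 1.0) + rng.uniform(0, 2 * np.pi))
    ph = cfg.ph_baseline + drift + 0.05 * rng.standard_normal(n)
    acid_floor = cfg.ph_baseline - cfg.ph_drop_depth          # ~3.0 by default
    nonacid_floor = 4.0 + 0.5                                 # never crosses pH 4
    for start, end, is_acid in events:
        floor = acid_floor if is_acid else max(nonacid_floor, acid_floor)
        depth = cfg.ph_baseline - floor
        onset = 5.0  # s to reach the dip floor
        dip = np.zeros(n)
        rise = (t >= start) & (t < start + onset)
        hold = (t >= start + onset) & (t < end)
        rec = t >= end
        dip[rise] = depth * (t[rise] - start) / onset
        dip[hold] = depth
        tau = max(cfg.ph_recovery_s / 3.0, 1.0)
        dip[rec] = depth * np.exp(-(t[rec] - end) / tau)
        ph = ph - dip
        if not is_acid:
            # construction guarantee: non-acid dips stay above the threshold
            ph[(t >= start) & (t < end + cfg.ph_recovery_s)] = np.maximum(
                ph[(t >= start) & (t < end + cfg.ph_recovery_s)], 4.2
            )
    return PhRecording(samples=np.clip(ph, 0.0, 14.0), fs=cfg.ph_fs)


def simulate_pair(cfg: SimConfig = SimConfig()) -> Tuple[Recording, PhRecording, GroundTruth]:
    """Generate one paired accelerometer + pH recording with ground truth.

    Identical configurations (including the seed) yield bit-identical
    sample arrays.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs

    accel = cfg.baseline_noise_uv * rng.standard_normal(n)
    if cfg.mains_amp_uv > 0:
        accel += cfg.mains_amp_uv * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))

    events = _place_intervals(
        rng, cfg.n_reflux_events, cfg.duration_s, cfg.event_duration_s, [], "reflux-event"
    )
    sigma_e = _band_noise_sigma(cfg.event_amp_uv, cfg.event_band, cfg.fs, cfg.fft_segment)
    labelled: List[Tuple[float, float, bool]] = []
    for start, end in events:
        i0, i1 = int(round(start * cfg.fs)), int(round(end * cfg.fs))
        burst = _band_limited_burst(rng, i1 - i0, cfg.event_band, sigma_e, cfg.fs)
        if cfg.rhythmic:
            period = 60.0 / cfg.rhythmic_rate_per_min
            tt = np.arange(i1 - i0) / cfg.fs
            gate = 0.5 * (1 - np.cos(2 * np.pi * tt / period))  # raised-cosine on/off
            burst = burst * gate
        accel[i0:i1] += burst
        labelled.append((start, end, bool(rng.random() < cfg.acid_fraction)))

    artifacts = _place_intervals(
        rng, cfg.n_artifacts, cfg.duration_s, cfg.artifact_duration_s, events, "artifact"
    )
    sigma_a = _band_noise_sigma(cfg.artifact_amp_uv, cfg.artifact_band, cfg.fs, cfg.fft_segment)
    for start, end in artifacts:
        i0, i1 = int(round(start * cfg.fs)), int(round(end * cfg.fs))
        accel[i0:i1] += _band_limited_burst(rng, i1 - i0, cfg.artifact_band, sigma_a, cfg.fs)

    ph = _ph_trace(rng, cfg, labelled)
    truth = GroundTruth(
        event_intervals=labelled,
        artifact_intervals=artifacts,
        expected_positive=cfg.n_reflux_events > 0,
    )
    return Recording(samples=accel, fs=cfg.fs), ph, truth


def cohort(
    n: int, prevalence: float, base_cfg: SimConfig = SimConfig()
) -> List[Tuple[Recording, PhRecording, GroundTruth]]:
    """Generate ``n`` paired recordings; ~``prevalence`` are event-bearing.

    All per-subject randomness derives from the master seed through a
    splittable counter scheme (NumPy SeedSequence.spawn), so the cohort is
    reproducible regardless of generation order.
    """
    if n <= 0:
        raise GenerationError("cohort size must be positive")
    master = np.random.SeedSequence(base_cfg.seed)
    assign_ss, subjects_ss = master.spawn(2)
    bearing = np.random.default_rng(assign_ss).random(n) < prevalence
    out = []
    for i, child in enumerate(subjects_ss.spawn(n)):
        seed_i = int(child.generate_state(1)[0] % (2**31))
        cfg_i = replace(
            base_cfg,
            seed=seed_i,
            n_reflux_events=base_cfg.n_reflux_events if bearing[i] else 0,
        )
        rec, ph, truth = simulate_pair(cfg_i)
        rec = replace(rec, subject_id=f"sim-{i + 1:03d}")
        ph = replace(ph, subject_id=f"sim-{i + 1:03d}")
        out.append((rec, ph, truth))
    return out
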