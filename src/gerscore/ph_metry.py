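"""Acid-reflux episode detection and the Boix-Ochoa composite pH score.

An acid episode is a maximal run of samples with pH below the acid
threshold (default 4.0) lasting at least ``min_episode_s`` (debouncing
probe-artifact spikes).  The composite is the DeMeester-style sum of six
normalized acid-exposure components — % time pH < 4 (total, upright,
supine), episode count, episodes of >= 5 min, and the longest episode —
each expressed as (observed - reference_mean)/reference_sd + 1 and
clamped at zero.  A composite strictly above the 16.6 cut-off is called
positive (significant acid reflux).

The published normative component means/SDs are not bundled: they are
required configuration.  ``identity_norms`` (mean 0, SD 1) supports
worked examples, and ``placeholder_norms`` is a synthetic stand-in for
exercising the pipeline — not normative data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, ValidationError
from .signal_io import PhRecording

__all__ = [
    "COMPONENTS",
    "PhConfig",
    "BoixOchoaResult",
    "identity_norms",
    "placeholder_norms",
    "detect_acid_episodes",
    "composite_from_components",
    "boix_ochoa",
]

#: The six composite components, in reporting order.
COMPONENTS = (
    "pct_time_acid",
    "pct_time_acid_upright",
    "pct_time_acid_supine",
    "n_episodes",
    "n_long_episodes",
    "longest_episode_min",
)

Norms = Dict[str, Tuple[float, float]]  # name -> (reference_mean, reference_sd)


def identity_norms() -> Norms:
    """Norms with mean 0, SD 1: the composite reduces to sum(component + 1)."""
    return {name: (0.0, 1.0) for name in COMPONENTS}


def placeholder_norms() -> Norms:
    """SYNTHETIC placeholder norms for pipeline exercises.

    These are not the published normative reference values; clinical use
    requires supplying the real component means/SDs in the configuration.
    """
    return {
        "pct_time_acid": (2.0, 1.5),
        "pct_time_acid_upright": (2.5, 2.0),
        "pct_time_acid_supine": (1.5, 1.5),
        "n_episodes": (15.0, 10.0),
        "n_long_episodes": (1.0, 1.0),
        "longest_episode_min": (5.0, 4.0),
    }


@dataclass(frozen=True)
class PhConfig:
    acid_threshold: float = 4.0     # pH; an episode requires pH strictly below
    min_episode_s: float = 15.0     # debounce: shorter dips are ignored
    long_episode_min: float = 5.0   # minutes; threshold for the "long" count
    cutoff: float = 16.6            # composite positivity cut-off (strict >)
    hysteresis: float = 0.0         # pH; episode ends at threshold + hysteresis
    component_norms: Optional[Norms] = None

    def __post_init__(self) -> None:
        if not 0 < self.acid_threshold < 14:
            raise ConfigurationError("acid_threshold must be in (0, 14)")
        if not self.cutoff > 0:
            raise ConfigurationError("cutoff must be positive")
        if self.component_norms is not None:
            missing = set(COMPONENTS) - set(self.component_norms)
            if missing:
                raise ConfigurationError(f"component_norms missing {sorted(missing)}")
            for name, (_, sd) in self.component_norms.items():
                if not sd > 0:
                    raise ConfigurationError(f"reference_sd for {name} must be > 0")


def detect_acid_episodes(
    ph: PhRecording, cfg: PhConfig = PhConfig()
) -> List[Tuple[float, float]]:
    """Maximal runs of pH < acid_threshold lasting >= min_episode_s.

    Returns half-open ``(start_s, end_s)`` intervals at run boundaries.
    With ``hysteresis > 0`` an ongoing episode only ends once pH recovers
    to at/above ``acid_threshold + hysteresis``.
    """
    x = ph.samples
    episodes: List[Tuple[float, float]] = []
    in_ep = False
    start = 0
    for i, v in enumerate(x):
        if not in_ep:
            if v < cfg.acid_threshold:
                in_ep = True
                start = i
        else:
            if v >= cfg.acid_threshold + cfg.hysteresis:
                if (i - start) / ph.fs >= cfg.min_episode_s:
                    episodes.append((start / ph.fs, i / ph.fs))
                in_ep = False
    if in_ep and (len(x) - start) / ph.fs >= cfg.min_episode_s:
        episodes.append((start / ph.fs, len(x) / ph.fs))
    return episodes


def composite_from_components(components: Sequence[float], norms: Norms) -> float:
    """Sum over components of max((observed - mean)/sd + 1, 0)."""
    total = 0.0
    for name, obs in zip(COMPONENTS, components):
        mean, sd = norms[name]
        total += max((obs - mean) / sd + 1.0, 0.0)
    return total


@dataclass
class BoixOchoaResult:
    subject_id: str
    pct_time_acid: float
    pct_time_acid_upright: float
    pct_time_acid_supine: float
    n_episodes: int
    n_long_episodes: int
    longest_episode: float          # minutes
    composite: float
    positive: bool                  # composite strictly > cutoff
    position_mode: str              # "tracked" or "supine-only (no position track)"
    duration_h: float
    short_study_flag: bool          # under 24 h: component statistics scale with duration
    norms_used: Dict[str, Tuple[float, float]]

    @property
    def components(self) -> Tuple[float, ...]:
        return (
            self.pct_time_acid,
            self.pct_time_acid_upright,
            self.pct_time_acid_supine,
            float(self.n_episodes),
            float(self.n_long_episodes),
            self.longest_episode,
        )


def boix_ochoa(
    ph: PhRecording,
    episodes: Optional[List[Tuple[float, float]]] = None,
    position_track: Optional[np.ndarray] = None,
    cfg: PhConfig = PhConfig(),
) -> BoixOchoaResult:
    """Compute the six component statistics and the composite score.

    ``position_track``, when given, is a per-sample array of ``"upright"`` /
    ``"supine"`` labels; when absent (infants are nursed supine), the
    upright and supine components both take the total-time value and the
    mode is recorded in the result.

    % time below threshold is computed from all samples (the classic
    definition); episode counts and durations use the debounced detector.
    """
    if cfg.component_norms is None:
        raise ConfigurationError(
            "PhConfig.component_norms is required: supply the normative "
            "(mean, SD) for each of the six components — the published "
            "reference values are not bundled with this package"
        )
    if len(ph.samples) == 0:
        raise ValidationError("empty pH recording")
    if episodes is None:
        episodes = detect_acid_episodes(ph, cfg)

    acid = ph.samples < cfg.acid_threshold
    pct_total = 100.0 * float(acid.mean())
    if position_track is not None:
        pos = np.asarray(position_track)
        if pos.shape != ph.samples.shape:
            raise ValidationError("position_track must match the pH trace length")
        up = pos == "upright"
        sup = ~up
        pct_up = 100.0 * float(acid[up].mean()) if up.any() else 0.0
        pct_sup = 100.0 * float(acid[sup].mean()) if sup.any() else 0.0
        mode = "tracked"
    else:
        pct_up = pct_sup = pct_total
        mode = "supine-only (no position track)"

    durations_min = [(e - s) / 60.0 for s, e in episodes]
    n_long = sum(1 for d in durations_min if d >= cfg.long_episode_min)
    longest = max(durations_min, default=0.0)

    comps = (pct_total, pct_up, pct_sup, float(len(episodes)), float(n_long), longest)
    composite = composite_from_components(comps, cfg.component_norms)
    duration_h = ph.duration_seconds / 3600.0
    return BoixOchoaResult(
        subject_id=ph.subject_id,
        pct_time_acid=pct_total,
        pct_time_acid_upright=pct_up,
        pct_time_acid_supine=pct_sup,
        n_episodes=len(episodes),
        n_long_episodes=n_long,
        longest_episode=longest,
        composite=composite,
        positive=composite > cfg.cutoff,
        position_mode=mode,
        duration_h=duration_h,
        short_study_flag=duration_h < 24.0,
        norms_used=dict(cfg.component_norms),
    )
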