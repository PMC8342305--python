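"""Shared fixtures and spectral measurement oracles."""
from __future__ import annotations

import numpy as np
import pytest

from gerscore.signal_io import Recording


def dft_amplitude(x: np.ndarray, freq: float, fs: float) -> float:
    """Single-sided amplitude at one frequency by direct DFT projection.

    Independent brute-force oracle: exact for tones spanning an integer
    number of cycles of ``freq`` in ``x``.
    """
    n = len(x)
    k = np.arange(n)
    return 2.0 * abs(np.sum(x * np.exp(-2j * np.pi * freq * k / fs))) / n


def fit_sinusoid_amplitude(x: np.ndarray, freq: float, fs: float) -> float:
    """Least-squares amplitude of a known-frequency sinusoid (phase-free)."""
    t = np.arange(len(x)) / fs
    A = np.column_stack([np.cos(2 * np.pi * freq * t), np.sin(2 * np.pi * freq * t)])
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    return float(np.hypot(*coef))


def tone(freq: float, amp: float, n: int, fs: float, phase: float = 0.0) -> Recording:
    t = np.arange(n) / fs
    return Recording(samples=amp * np.sin(2 * np.pi * freq * t + phase), fs=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(20210323)
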