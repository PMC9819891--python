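"""Shared fixtures: synthesized tones, click tracks and triads.

Audio fixtures are generated programmatically; durations default to a
few seconds for unit tests (feature functions only need a handful of
STFT frames) and 15 s where a test exercises the full clip contract.
"""

from __future__ import annotations

import numpy as np
import pytest

from emomap.types import AudioClip

FS = 44100
SEMITONE = 2.0 ** (1.0 / 12.0)


def make_tone(freq: float, duration: float = 15.0, amp: float = 0.5, fs: int = FS) -> AudioClip:
    t = np.arange(int(fs * duration)) / fs
    return AudioClip(samples=amp * np.sin(2 * np.pi * freq * t), fs=fs)


def make_click_track(bpm: float, duration: float = 15.0, fs: int = FS) -> AudioClip:
    """Damped 1 kHz bursts every beat."""
    n = int(fs * duration)
    x = np.zeros(n)
    period = int(round(fs * 60.0 / bpm))
    burst_len = int(0.02 * fs)
    tb = np.arange(burst_len) / fs
    burst = np.sin(2 * np.pi * 1000.0 * tb) * np.exp(-tb / 0.004)
    for start in range(0, n - burst_len, period):
        x[start : start + burst_len] += burst
    return AudioClip(samples=x, fs=fs)


def make_triad(
    root: float, minor: bool = False, duration: float = 15.0, fs: int = FS,
    harmonics: bool = False,
) -> AudioClip:
    """Root + third + fifth as sines (optionally with 2nd/3rd harmonics)."""
    t = np.arange(int(fs * duration)) / fs
    intervals = [0, 3 if minor else 4, 7]
    x = np.zeros(t.size)
    partials = ((1, 1.0), (2, 0.5), (3, 0.25)) if harmonics else ((1, 1.0),)
    for s in intervals:
        f = root * SEMITONE**s
        for h, a in partials:
            x += a * np.sin(2 * np.pi * f * h * t)
    return AudioClip(samples=0.25 * x, fs=fs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
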