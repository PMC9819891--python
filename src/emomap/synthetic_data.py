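"""Seeded synthetic EEG, music and transition-record generators.

Every pipeline stage in the package can be exercised end-to-end on
data with known ground truth:

* EEG trials are sums of band-limited sinusoids (random phase) whose
  per-band amplitudes depend on the class, plus white Gaussian noise —
  the class structure lives exactly where the band-power features
  look, so recovery validates the denoise/decompose/PSD chain.
* Music clips combine a click train at a class tempo, a major or
  minor triad with harmonics, spectrally tilted noise, and an
  optional detuned beating partial — one controllable handle per
  feature family (rhythm, harmony, timbre, roughness, intensity).
* Transition records are i.i.d. draws from a known conditional
  transition matrix P(after | before, music type).

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from emomap.types import (
    AudioClip,
    EEGRecording,
    InvalidInputError,
    MUSIC_EMOTIONS,
    TransitionRecord,
)

#: 32-channel 10-20 montage (the usual EEG-cap ordering).
CHANNELS_32 = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]

#: Carrier frequency range per band for the EEG simulator, Hz. Each
#: band's oscillatory content is a dense sum of random-phase sinusoids
#: across this range (0.5 Hz spacing), approximating the finite
#: bandwidth of real EEG rhythms; a single pure tone would concentrate
#: all band power in a few PSD bins and misrepresent band-power
#: features. The gamma range stops at 44 Hz, inside the 4-45 Hz
#: analysis bandpass.
BAND_RANGES = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 44.0),
}

#: Sinusoid spacing within a band carrier, Hz.
CARRIER_SPACING = 0.5


def _band_carrier(
    f_low: float, f_high: float, amplitude: float, t: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random-phase sinusoid comb across [f_low, f_high] with total RMS
    equal to a single sinusoid of the given amplitude."""
    freqs = np.arange(f_low + CARRIER_SPACING, f_high, CARRIER_SPACING)
    x = np.zeros(t.size)
    for f in freqs:
        x += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    return amplitude * x / np.sqrt(freqs.size)


def _default_band_profiles(n_classes: int, boost: float, baseline: float) -> list[dict[str, float]]:
    """Class k boosts band k (cycling through theta..gamma)."""
    bands = list(BAND_RANGES)
    profiles = []
    for k in range(n_classes):
        profile = {b: baseline for b in bands}
        profile[bands[k % len(bands)]] = boost
        profiles.append(profile)
    return profiles


@dataclass
class EEGSimSpec:
    """Configuration for the synthetic EEG generator.

    Amplitudes are in microvolts; the default 3:1 boosted-to-baseline
    band-amplitude ratio with unit noise gives trials whose class is
    recoverable from band powers but not trivially visible per sample.
    """

    n_classes: int = 4
    trials_per_class: int = 40
    n_channels: int = 32
    fs: float = 128.0
    duration_s: float = 10.0
    boost_amplitude: float = 3.0
    baseline_amplitude: float = 1.0
    band_profiles: list[dict[str, float]] | None = None
    informative_channels: list[str] | None = None  # None = all channels
    noise_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise InvalidInputError("n_classes must be >= 1")
        if self.trials_per_class < 1:
            raise InvalidInputError("trials_per_class must be >= 1")
        if not 1 <= self.n_channels <= len(CHANNELS_32):
            raise InvalidInputError(
                f"n_channels must lie in [1, {len(CHANNELS_32)}]"
            )
        if self.fs <= 0 or self.duration_s <= 0:
            raise InvalidInputError("fs and duration_s must be positive")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")
        if self.boost_amplitude < 0 or self.baseline_amplitude < 0:
            raise InvalidInputError("amplitudes must be >= 0")
        channels = CHANNELS_32[: self.n_channels]
        if self.informative_channels is not None:
            missing = set(self.informative_channels) - set(channels)
            if missing:
                raise InvalidInputError(
                    f"informative_channels not in montage: {sorted(missing)}"
                )
        if self.band_profiles is not None:
            if len(self.band_profiles) != self.n_classes:
                raise InvalidInputError("band_profiles must have one entry per class")
            for p in self.band_profiles:
                if set(p) != set(BAND_RANGES):
                    raise InvalidInputError(
                        f"band profile keys must be {sorted(BAND_RANGES)}"
                    )
                if any(v < 0 for v in p.values()):
                    raise InvalidInputError("band amplitudes must be >= 0")


def simulate_eeg(
    spec: EEGSimSpec,
) -> tuple[list[EEGRecording], list[str], dict]:
    """Generate seeded synthetic EEG trials with class-dependent band powers.

    Returns (recordings, labels, ground_truth); the ground-truth
    manifest records the per-class band amplitudes and informative
    channels actually used.
    """
    rng = np.random.default_rng(spec.seed)
    channels = CHANNELS_32[: spec.n_channels]
    informative = (
        spec.informative_channels if spec.informative_channels is not None else channels
    )
    profiles = (
        spec.band_profiles
        if spec.band_profiles is not None
        else _default_band_profiles(
            spec.n_classes, spec.boost_amplitude, spec.baseline_amplitude
        )
    )
    n = int(round(spec.fs * spec.duration_s))
    t = np.arange(n) / spec.fs
    recordings: list[EEGRecording] = []
    labels: list[str] = []
    trial = 0
    for k in range(spec.n_classes):
        label = f"class_{k}"
        for _ in range(spec.trials_per_class):
            samples = np.empty((spec.n_channels, n))
            for ci, ch in enumerate(channels):
                x = rng.normal(0.0, spec.noise_sigma, n)
                for band, (f_low, f_high) in BAND_RANGES.items():
                    amp = (
                        profiles[k][band]
                        if ch in informative
                        else spec.baseline_amplitude
                    )
                    x = x + _band_carrier(f_low, f_high, amp, t, rng)
                samples[ci] = x
            recordings.append(
                EEGRecording(
                    channel_names=channels,
                    samples=samples,
                    fs=spec.fs,
                    trial_id=f"trial_{trial:04d}",
                    subject_id="synthetic",
                )
            )
            labels.append(label)
            trial += 1
    ground_truth = {
        "band_profiles": {f"class_{k}": profiles[k] for k in range(spec.n_classes)},
        "informative_channels": list(informative),
        "band_ranges_hz": dict(BAND_RANGES),
        "noise_sigma": spec.noise_sigma,
        "fs": spec.fs,
        "duration_s": spec.duration_s,
        "seed": spec.seed,
    }
    return recordings, labels, ground_truth


# --- music -----------------------------------------------------------------

SEMITONE = 2.0 ** (1.0 / 12.0)


@dataclass
class AudioClassProfile:
    """Synthesis parameters for one music emotion class."""

    tempo_bpm: float
    tilt_db_per_octave: float
    mode: str  # "major" | "minor"
    detune_hz: float
    level: float
    root_hz: float = 220.0

    def __post_init__(self) -> None:
        if not 60.0 <= self.tempo_bpm <= 180.0:
            raise InvalidInputError(
                f"tempo must lie in [60, 180] BPM, got {self.tempo_bpm}"
            )
        if not 0.0 < self.level <= 1.0:
            raise InvalidInputError(f"level must lie in (0, 1], got {self.level}")
        if self.mode not in ("major", "minor"):
            raise InvalidInputError(f"mode must be 'major' or 'minor', got {self.mode!r}")
        if self.detune_hz < 0:
            raise InvalidInputError("detune_hz must be >= 0")


#: Default per-class profiles. Each feature family separates at least one
#: class pair: tempos are >5 BPM apart (rhythm), relaxation/sadness are
#: dull and quiet (centroid/RMS), disgust is bright and heavily detuned
#: (roughness), joy-like classes are major, fear-like minor (mode).
DEFAULT_AUDIO_PROFILES: dict[str, AudioClassProfile] = {
    "anger":      AudioClassProfile(168.0, -1.0, "minor", 18.0, 0.80),
    "confidence": AudioClassProfile(123.0, -2.0, "major",  0.0, 0.85),
    "disgust":    AudioClassProfile(132.0,  0.0, "minor", 30.0, 0.80),
    "fear":       AudioClassProfile(96.0,  -1.5, "minor", 14.0, 0.75),
    "joy":        AudioClassProfile(140.0, -2.5, "major",  0.0, 0.80),
    "passion":    AudioClassProfile(150.0, -3.0, "major",  6.0, 0.85),
    "relaxation": AudioClassProfile(72.0,  -6.0, "major",  0.0, 0.55),
    "sadness":    AudioClassProfile(60.0,  -5.0, "minor",  0.0, 0.60),
}


@dataclass
class AudioSimSpec:
    """Configuration for the synthetic music generator."""

    profiles: dict[str, AudioClassProfile] = field(
        default_factory=lambda: dict(DEFAULT_AUDIO_PROFILES)
    )
    clips_per_class: int = 40
    duration_s: float = 15.0
    fs: int = 44100
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.profiles:
            raise InvalidInputError("profiles must be non-empty")
        if self.clips_per_class < 1:
            raise InvalidInputError("clips_per_class must be >= 1")
        if self.duration_s <= 0 or self.fs <= 0:
            raise InvalidInputError("duration_s and fs must be positive")


def synthesize_clip(
    profile: AudioClassProfile,
    duration_s: float = 15.0,
    fs: int = 44100,
    rng: np.random.Generator | None = None,
    source_id: str = "",
    clip_index: int = 0,
) -> AudioClip:
    """Render one clip from a class profile.

    Components: a click train at the class tempo (damped 1 kHz bursts),
    a triad (root + major/minor third + fifth, each with three
    harmonics), noise with the class spectral tilt, and — when
    ``detune_hz > 0`` — a partial beating against the fifth.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs

    # triad partials with harmonics
    third = 4 if profile.mode == "major" else 3
    note_freqs = [
        profile.root_hz,
        profile.root_hz * SEMITONE**third,
        profile.root_hz * SEMITONE**7,
    ]
    x = np.zeros(n)
    for f0 in note_freqs:
        for h, amp in ((1, 1.0), (2, 0.5), (3, 0.25)):
            x += amp * np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi))
    if profile.detune_hz > 0:
        beat_f = note_freqs[2] + profile.detune_hz
        x += 1.0 * np.sin(2 * np.pi * beat_f * t + rng.uniform(0, 2 * np.pi))

    # click train: 20 ms damped 1 kHz bursts at the beat period
    period = int(round(fs * 60.0 / profile.tempo_bpm))
    burst_len = int(0.02 * fs)
    tb = np.arange(burst_len) / fs
    burst = np.sin(2 * np.pi * 1000.0 * tb) * np.exp(-tb / 0.004)
    clicks = np.zeros(n)
    for start in range(0, n - burst_len, period):
        clicks[start : start + burst_len] += burst
    x += 6.0 * clicks

    # spectrally tilted noise: gain(f) = (f/1000)^(tilt/6.02) dB/octave
    noise = rng.normal(0.0, 1.0, n)
    spectrum = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    exponent = profile.tilt_db_per_octave / (20.0 * np.log10(2.0))
    with np.errstate(divide="ignore"):
        gain = np.where(freqs > 0, (freqs / 1000.0) ** exponent, 0.0)
    gain[freqs < 20.0] = 0.0  # keep subsonic rumble out
    tilted = np.fft.irfft(spectrum * gain, n)
    tilted_rms = np.sqrt(np.mean(tilted**2))
    if tilted_rms > 0:
        x += 0.8 * tilted / tilted_rms

    # level sets the RMS (scaled to a typical music loudness) so the
    # intensity feature depends on the class profile, not on how many
    # clicks happen to fall in the clip; a peak guard prevents clipping
    rms_now = np.sqrt(np.mean(x**2))
    if rms_now > 0:
        x = x * (0.2 * profile.level / rms_now)
    peak = np.max(np.abs(x))
    if peak > 0.99:
        x = x * (0.99 / peak)
    return AudioClip(samples=x, fs=fs, source_id=source_id, clip_index=clip_index)


def iter_music_clips(spec: AudioSimSpec) -> Iterator[tuple[AudioClip, str]]:
    """Yield (clip, label) pairs one at a time (memory-friendly)."""
    rng = np.random.default_rng(spec.seed)
    for label in sorted(spec.profiles):
        profile = spec.profiles[label]
        for i in range(spec.clips_per_class):
            yield (
                synthesize_clip(
                    profile,
                    spec.duration_s,
                    spec.fs,
                    rng,
                    source_id=label,
                    clip_index=i,
                ),
                label,
            )


def simulate_music(spec: AudioSimSpec) -> tuple[list[AudioClip], list[str]]:
    """Materialize all clips; prefer :func:`iter_music_clips` for large specs."""
    clips, labels = [], []
    for clip, label in iter_music_clips(spec):
        clips.append(clip)
        labels.append(label)
    return clips, labels


# --- transitions -----------------------------------------------------------


@dataclass
class TransitionSimSpec:
    """A known conditional transition matrix plus a sample size."""

    #: matrix[(before, music_type)] = {after: probability}
    matrix: dict[tuple[str, str], dict[str, float]]
    n_records: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.matrix:
            raise InvalidInputError("transition matrix is empty")
        if self.n_records < 1:
            raise InvalidInputError("n_records must be >= 1")
        for key, row in self.matrix.items():
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise InvalidInputError(
                    f"probabilities for {key} sum to {total}, not 1"
                )
            if any(p < 0 for p in row.values()):
                raise InvalidInputError(f"negative probability under {key}")


def default_transition_matrix() -> dict[tuple[str, str], dict[str, float]]:
    """A dense example matrix: music moves the listener toward its own mood.

    Joy-type music lifts a fearful state toward surprise and intimacy;
    sad music pulls an intimate state toward fear and sadness. Two
    conditioning keys keep per-key counts high enough that a few
    thousand records pin every cell to within a few percent.
    """
    return {
        ("fear", "joy"): {"surprise": 0.5, "intimacy": 0.3, "fear": 0.15, "sadness": 0.05},
        ("intimacy", "sadness"): {"fear": 0.5, "sadness": 0.3, "intimacy": 0.15, "surprise": 0.05},
    }


def simulate_transitions(spec: TransitionSimSpec) -> list[TransitionRecord]:
    """Draw transition records i.i.d. from the spec's conditional matrix.

    Conditioning keys (before, music_type) are sampled uniformly; the
    after state follows the key's conditional row.
    """
    rng = np.random.default_rng(spec.seed)
    keys = sorted(spec.matrix)
    records: list[TransitionRecord] = []
    key_idx = rng.integers(0, len(keys), size=spec.n_records)
    for ki in key_idx:
        before, music_type = keys[ki]
        row = spec.matrix[(before, music_type)]
        afters = sorted(row)
        probs = np.array([row[a] for a in afters])
        after = afters[rng.choice(len(afters), p=probs / probs.sum())]
        records.append(TransitionRecord(before=before, music_type=music_type, after=after))
    return records
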