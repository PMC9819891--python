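"""Per-clip music feature extraction.

Music is merged to mono, cut into non-overlapping 15-second clips, and
each clip is summarised by a 21-dimensional feature vector covering
timbre (13 MFCCs, spectral centroid, spectral flux), temporal
structure (zero-crossing count), intensity (RMS), rhythm (tempo in BPM
and pulse clarity), harmony (a signed major/minor mode score) and
sensory roughness. Frame-level quantities are computed on a Hann STFT
(2048-sample frames, 1024 hop at 44.1 kHz) and aggregated to the clip
by averaging over frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.fft import rfft

from emomap.types import (
    AudioClip,
    InvalidInputError,
    MUSIC_FEATURE_NAMES,
    MusicFeatureVector,
)

FRAME_LENGTH = 2048
HOP_LENGTH = 1024
CLIP_SECONDS = 15
CLIP_FS = 44100

#: Mel filterbank / cepstrum configuration.
N_MELS = 26
N_MFCC = 13
LOG_ENERGY_FLOOR = 1e-10

#: Tempo search range, beats per minute.
BPM_MIN = 60.0
BPM_MAX = 180.0

#: Krumhansl-Kessler probe-tone key profiles (C-rooted; index = pitch class).
KK_MAJOR = np.array(
    [6.35, 2.23, 3.48, 2.33, 4.38, 4.09, 2.52, 5.19, 2.39, 3.66, 2.29, 2.88]
)
KK_MINOR = np.array(
    [6.33, 2.68, 3.52, 5.38, 2.60, 3.53, 2.54, 4.75, 3.98, 2.69, 3.34, 3.17]
)


@dataclass
class STFTFrames:
    """Magnitude spectrogram with its framing parameters."""

    magnitudes: np.ndarray  # frames x bins, >= 0
    frame_length: int
    hop: int
    bin_freqs: np.ndarray  # Hz

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]


def merge_stereo(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Average the two channels sample-wise, preserving all content."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise InvalidInputError(
            f"channel length mismatch: {left.shape} vs {right.shape}"
        )
    return (left + right) / 2.0


def segment_clips(
    mono: np.ndarray, fs: int = CLIP_FS, clip_seconds: float = CLIP_SECONDS,
    source_id: str = "",
) -> list[AudioClip]:
    """Cut a mono signal into consecutive fixed-length clips.

    The number of clips is ``trunc(length / fs / clip_seconds)``; the
    remainder past the last whole clip is discarded.
    """
    if fs <= 0:
        raise InvalidInputError("fs must be positive")
    mono = np.asarray(mono, dtype=float)
    clip_len = int(fs * clip_seconds)
    n_clips = int(mono.size / fs / clip_seconds)
    return [
        AudioClip(
            samples=mono[i * clip_len : (i + 1) * clip_len],
            fs=fs,
            source_id=source_id,
            clip_index=i,
        )
        for i in range(n_clips)
    ]


def stft_magnitudes(
    clip: AudioClip, frame_length: int = FRAME_LENGTH, hop: int = HOP_LENGTH
) -> STFTFrames:
    """Hann-windowed magnitude STFT, frames x bins."""
    x = clip.samples
    if x.size < frame_length:
        raise InvalidInputError("clip shorter than one analysis frame")
    n_frames = 1 + (x.size - frame_length) // hop
    idx = np.arange(frame_length)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx] * np.hanning(frame_length)[None, :]
    mags = np.abs(rfft(frames, axis=1))
    bin_freqs = np.arange(mags.shape[1]) * clip.fs / frame_length
    return STFTFrames(
        magnitudes=mags, frame_length=frame_length, hop=hop, bin_freqs=bin_freqs
    )


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, fs: int, f_min: float = 0.0, f_max: float | None = None
) -> np.ndarray:
    """Triangular mel filterbank, filters x rfft-bins, peak-normalized to 1."""
    f_max = f_max if f_max is not None else fs / 2.0
    mel_edges = np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_filters + 2)
    hz_edges = np.asarray(_mel_to_hz(mel_edges))
    bin_freqs = np.arange(n_fft // 2 + 1) * fs / n_fft
    fb = np.zeros((n_filters, bin_freqs.size))
    for m in range(n_filters):
        lo, ctr, hi = hz_edges[m], hz_edges[m + 1], hz_edges[m + 2]
        rising = (bin_freqs - lo) / max(ctr - lo, 1e-12)
        falling = (hi - bin_freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def mfcc(clip: AudioClip, L: int = N_MFCC, M: int = N_MELS) -> np.ndarray:
    """Mean mel-frequency cepstral coefficients 1..L over frames.

    Per frame: power spectrum -> M triangular mel filters -> log
    energies E(m) (floored so silence stays finite) -> cepstrum
    ``c_n = sum_m E(m) cos(pi n (m - 0.5) / M)`` for n = 1..L.
    """
    frames = stft_magnitudes(clip)
    power = frames.magnitudes**2
    fb = mel_filterbank(M, frames.frame_length, clip.fs)
    energies = power @ fb.T  # frames x M
    log_e = np.log(np.maximum(energies, LOG_ENERGY_FLOOR))
    n = np.arange(1, L + 1)[:, None]  # L x 1
    m = np.arange(1, M + 1)[None, :]  # 1 x M
    dct_basis = np.cos(np.pi * n * (m - 0.5) / M)  # L x M
    coeffs = log_e @ dct_basis.T  # frames x L
    return coeffs.mean(axis=0)


def spectral_centroid(clip: AudioClip) -> float:
    """Energy-weighted mean frequency of the clip's STFT, in Hz.

    Frames are pooled by total energy; an all-zero clip yields 0 Hz.
    """
    frames = stft_magnitudes(clip)
    power = frames.magnitudes**2
    total = power.sum()
    if total <= 0:
        return 0.0
    return float((power @ frames.bin_freqs).sum() / total)


def spectral_flux(clip: AudioClip) -> float:
    """Mean squared change of unit-normalized magnitude spectra.

    Each frame's magnitude spectrum is normalized to unit sum; the
    flux is ``sum_k (N_i(k) - N_{i-1}(k))^2`` averaged over
    consecutive frame pairs.
    """
    frames = stft_magnitudes(clip)
    if frames.n_frames < 2:
        raise InvalidInputError("spectral flux needs at least 2 frames")
    mags = frames.magnitudes
    sums = mags.sum(axis=1, keepdims=True)
    norm = np.where(sums > 0, mags / np.maximum(sums, 1e-30), 0.0)
    diffs = np.diff(norm, axis=0)
    return float((diffs**2).sum(axis=1).mean())


def zero_crossings(clip: AudioClip) -> int:
    """Total sign-change count over the clip.

    ``(1/2) sum |sign(x_m) - sign(x_{m-1})|`` with sign(x) = 1 for
    x >= 0 and -1 otherwise.
    """
    x = clip.samples
    if x.size < 2:
        raise InvalidInputError("need at least 2 samples")
    s = np.where(x >= 0, 1, -1)
    return int(np.abs(np.diff(s)).sum() // 2)


def rms(clip: AudioClip) -> float:
    """Root mean square level of the clip."""
    x = clip.samples
    if x.size < 1:
        raise InvalidInputError("empty clip")
    return float(np.sqrt(np.mean(x**2)))


#: Onset analysis uses a finer grid than the feature STFT so beat
#: periods are not quantized away (hop 256 -> ~172 Hz envelope rate).
ONSET_FRAME = 1024
ONSET_HOP = 256
#: Envelope smoothing kernel width (frames); suppresses the phase
#: sensitivity of click alignment within frames.
_ONSET_SMOOTH = 9
#: Among autocorrelation peaks within this fraction of the maximum, the
#: smallest lag wins - the standard guard against period-doubling.
_ACF_PEAK_TOLERANCE = 0.9


def onset_envelope(clip: AudioClip) -> tuple[np.ndarray, float]:
    """Half-wave-rectified spectral-flux onset strength per frame.

    Returns (envelope, frame rate in Hz). The envelope is lightly
    smoothed with a Hann kernel.
    """
    frames = stft_magnitudes(clip, frame_length=ONSET_FRAME, hop=ONSET_HOP)
    diffs = np.diff(frames.magnitudes, axis=0)
    env = np.clip(diffs, 0.0, None).sum(axis=1)
    kernel = np.hanning(_ONSET_SMOOTH)
    env = np.convolve(env, kernel / kernel.sum(), mode="same")
    return env, clip.fs / frames.hop


def estimate_bpm(clip: AudioClip) -> tuple[float, float]:
    """Tempo and pulse clarity from the onset-envelope autocorrelation.

    The onset envelope is mean-removed and autocorrelated; among
    autocorrelation peaks within 90% of the in-range maximum the
    smallest lag is taken as the beat period T (parabolic
    interpolation refines it) and BPM = 60 / T. Pulse clarity is the
    peak height normalized by the lag-0 value, in [0, 1]. A degenerate
    (silent) clip returns the range midpoint with clarity 0.
    """
    env, frame_rate = onset_envelope(clip)
    env = env - env.mean()
    if not np.any(env):
        return (BPM_MIN + BPM_MAX) / 2.0, 0.0
    acf = np.correlate(env, env, mode="full")[env.size - 1 :]
    lag_min = int(np.floor(frame_rate * 60.0 / BPM_MAX))
    lag_max = int(np.ceil(frame_rate * 60.0 / BPM_MIN))
    lag_max = min(lag_max, acf.size - 2)
    if lag_min < 1 or lag_min >= lag_max or acf[0] <= 0:
        return (BPM_MIN + BPM_MAX) / 2.0, 0.0
    window = acf[lag_min : lag_max + 1]
    cutoff = _ACF_PEAK_TOLERANCE * window.max()
    peak = None
    for offset in np.flatnonzero(window >= cutoff):
        lag = lag_min + int(offset)
        if acf[lag] >= acf[lag - 1] and acf[lag] >= acf[lag + 1]:
            peak = lag
            break
    if peak is None:
        peak = lag_min + int(np.argmax(window))
    y0, y1, y2 = acf[peak - 1], acf[peak], acf[peak + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    lag_refined = peak + float(np.clip(delta, -0.5, 0.5))
    bpm = float(np.clip(60.0 * frame_rate / lag_refined, BPM_MIN, BPM_MAX))
    clarity = float(np.clip(acf[peak] / acf[0], 0.0, 1.0))
    return bpm, clarity


#: Chroma needs finer frequency resolution than the feature STFT: at
#: 2048 samples the ~21.5 Hz bins conflate semitones below ~370 Hz.
CHROMA_FRAME = 8192
CHROMA_HOP = 4096


def chroma(clip: AudioClip, f_min: float = 55.0, f_max: float = 4186.0) -> np.ndarray:
    """12-bin pitch-class energy profile from the STFT (C = bin 0)."""
    frames = stft_magnitudes(clip, frame_length=CHROMA_FRAME, hop=CHROMA_HOP)
    power = frames.magnitudes**2
    freqs = frames.bin_freqs
    mask = (freqs >= f_min) & (freqs <= f_max)
    if not np.any(mask):
        return np.zeros(12)
    # A4 = 440 Hz is pitch class 9 (A), so offset by +9 from A-relative.
    pcs = (np.round(12 * np.log2(freqs[mask] / 440.0)).astype(int) + 9) % 12
    profile = np.zeros(12)
    np.add.at(profile, pcs, power[:, mask].sum(axis=0))
    return profile


def estimate_mode(clip: AudioClip) -> float:
    """Signed major-vs-minor tonality score.

    Correlates the clip's chroma with the 12 rotations of the
    Krumhansl-Kessler major and minor key profiles; the score is
    (best major correlation) - (best minor correlation), positive for
    major-mode content. Silence yields 0.
    """
    c = chroma(clip)
    if c.sum() <= 0 or np.allclose(c, c[0]):
        return 0.0

    def best_corr(profile: np.ndarray) -> float:
        return max(
            float(np.corrcoef(c, np.roll(profile, r))[0, 1]) for r in range(12)
        )

    return best_corr(KK_MAJOR) - best_corr(KK_MINOR)


#: Plomp-Levelt dissonance-curve constants (Sethares parameterization).
_PL_B1 = 3.5
_PL_B2 = 5.75
_PL_DSTAR = 0.24
_PL_S1 = 0.021
_PL_S2 = 19.0

#: Per-frame peak picking for roughness: keep at most this many partials.
_MAX_PEAKS = 16
_PEAK_REL_THRESHOLD = 1e-4


def _pl_dissonance(f: np.ndarray, a: np.ndarray) -> float:
    """Total pairwise Plomp-Levelt dissonance for one frame's partials."""
    order = np.argsort(f)
    f, a = f[order], a[order]
    total = 0.0
    for i in range(f.size - 1):
        s = _PL_DSTAR / (_PL_S1 * f[i] + _PL_S2)
        df = f[i + 1 :] - f[i]
        amp = a[i] * a[i + 1 :]
        total += float(
            np.sum(amp * (np.exp(-_PL_B1 * s * df) - np.exp(-_PL_B2 * s * df)))
        )
    return total


def roughness(clip: AudioClip) -> float:
    """Sensory dissonance from beating spectral partials.

    Per frame, spectral peaks are detected and every peak pair
    contributes a Plomp-Levelt dissonance term (maximal for partials
    roughly a quarter critical band apart, vanishing for unison and
    wide separations); the clip value is the frame average. A lone
    pure tone or silence scores ~0.
    """
    frames = stft_magnitudes(clip)
    mags = frames.magnitudes
    global_max = mags.max()
    if global_max <= 0:
        return 0.0
    threshold = global_max * _PEAK_REL_THRESHOLD
    total = 0.0
    for frame in mags:
        peaks, props = sps.find_peaks(frame, height=threshold)
        if peaks.size < 2:
            continue
        heights = props["peak_heights"]
        if peaks.size > _MAX_PEAKS:
            keep = np.argsort(heights)[-_MAX_PEAKS:]
            peaks, heights = peaks[keep], heights[keep]
        # normalize amplitudes so the measure reflects spectral shape,
        # not absolute level, comparably across frames
        amps = heights / global_max
        total += _pl_dissonance(frames.bin_freqs[peaks], amps)
    return total / frames.n_frames


def extract_music_features(clip: AudioClip) -> MusicFeatureVector:
    """The full 21-dimensional per-clip feature vector.

    Order: mfcc_1..mfcc_13, spectral_centroid, spectral_flux,
    zero_crossings, rms, bpm, bpm_intensity, mode, roughness.
    """
    coeffs = mfcc(clip)
    bpm, clarity = estimate_bpm(clip)
    values = np.concatenate(
        [
            coeffs,
            [
                spectral_centroid(clip),
                spectral_flux(clip),
                float(zero_crossings(clip)),
                rms(clip),
                bpm,
                clarity,
                estimate_mode(clip),
                roughness(clip),
            ],
        ]
    )
    return MusicFeatureVector(values=values)
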