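"""Sub-band decomposition and average log-PSD features.

A 5-level db4 discrete wavelet transform partitions [1, fs/2] into the
five canonical EEG bands (at fs = 128 Hz: delta 1-4, theta 4-8,
alpha 8-16, beta 16-32, gamma 32-64). Each band signal is
reconstructed from that band's coefficients alone, its PSD is
estimated with Welch's averaged periodogram (Hamming window, ~8
segments, 50% overlap), and the feature is the mean of 10*log10(Pxx)
over PSD points, in dB. The delta band is dropped (sleep-related, and
removed by the 4-45 Hz bandpass), leaving a
channels x {theta, alpha, beta, gamma} feature vector.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from emomap import eeg_preprocessing as prep
from emomap.types import (
    BandDecomposition,
    DenoiseConfig,
    EEGFeatureVector,
    EEGRecording,
    InvalidInputError,
    PSDEstimate,
    SubbandScheme,
)

#: Band names, coarsest to finest decomposition level.
BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")

#: Bands used as features (delta excluded).
FEATURE_BANDS = ("theta", "alpha", "beta", "gamma")

#: Number of sub-bands; the underlying DWT depth is one less (a 4-level
#: db4 transform yields cA4 + cD4..cD1 = five band components).
DECOMPOSITION_LEVELS = 5
DWT_LEVEL = DECOMPOSITION_LEVELS - 1
WAVELET = "db4"
BOUNDARY_MODE = "symmetric"

#: PSD values are floored here before the log so silent bands stay finite.
PSD_FLOOR = 1e-12

WELCH_SEGMENTS = 8
WELCH_OVERLAP = 0.5


def subband_ranges(fs: float, levels: int = DECOMPOSITION_LEVELS) -> SubbandScheme:
    """Dyadic sub-band edges for a ``levels``-deep wavelet decomposition.

    The approximation at the deepest level spans [1, fs/2^levels]; each
    detail level k spans [fs/2^(k+1), fs/2^k]. For fs = 128 and five
    levels this reproduces delta 1-4 (A5... labelled A4 by convention
    below), theta 4-8 (D4), alpha 8-16 (D3), beta 16-32 (D2) and
    gamma 32-64 Hz (D1).
    """
    if fs <= 0 or levels < 1:
        raise InvalidInputError("fs must be positive and levels >= 1")
    if fs / 2**levels < 1:
        raise InvalidInputError(
            f"fs={fs} too low for {levels} levels (approximation band below 1 Hz)"
        )
    level_labels = [f"A{levels - 1}"] + [f"D{k}" for k in range(levels - 1, 0, -1)]
    bands: list[tuple[str, str, float, float]] = []
    names = BAND_NAMES if levels == 5 else tuple(f"band{i}" for i in range(levels))
    # Approximation band; lower edge pinned at 1 Hz by convention.
    bands.append((names[0], level_labels[0], 1.0, fs / 2**levels))
    for i in range(1, levels):
        k = levels - i
        bands.append((names[i], level_labels[i], fs / 2 ** (k + 1), fs / 2**k))
    return SubbandScheme(fs=fs, bands=bands)


def wavelet_band_decompose(signal: np.ndarray, fs: float) -> list[BandDecomposition]:
    """Split a signal into five band-limited components via the DWT.

    Each component is the inverse transform of one coefficient level
    with all others zeroed, so the five components sum back to the
    input exactly (linearity + perfect reconstruction).
    """
    x = np.asarray(signal, dtype=float)
    min_len = 2**DECOMPOSITION_LEVELS
    if x.size < min_len:
        raise InvalidInputError(
            f"signal too short for a {DECOMPOSITION_LEVELS}-band decomposition "
            f"(need >= {min_len} samples, got {x.size})"
        )
    scheme = subband_ranges(fs, DECOMPOSITION_LEVELS)
    # [cA4, cD4, cD3, cD2, cD1] aligns index-by-index with scheme.bands
    coeffs = pywt.wavedec(x, WAVELET, mode=BOUNDARY_MODE, level=DWT_LEVEL)
    out: list[BandDecomposition] = []
    for i, (name, label, _, _) in enumerate(scheme.bands):
        isolated = [np.zeros_like(c) for c in coeffs]
        isolated[i] = coeffs[i]
        band = pywt.waverec(isolated, WAVELET, mode=BOUNDARY_MODE)[: x.size]
        out.append(BandDecomposition(band_name=name, level_label=label, band_signal=band))
    return out


def welch_psd(
    signal: np.ndarray,
    fs: float,
    n_segments: int = WELCH_SEGMENTS,
    overlap: float = WELCH_OVERLAP,
) -> PSDEstimate:
    """Welch averaged periodogram with a Hamming window.

    The window length is chosen so ``n_segments`` half-overlapping
    segments tile the signal: ``nperseg = floor(2N / (n_segments + 1))``
    at 50% overlap; trailing samples that do not fill a segment are
    clipped.
    """
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise InvalidInputError("signal too short for a PSD estimate")
    denom = 1 + (n_segments - 1) * (1 - overlap)
    nperseg = max(2, int(x.size / denom))
    nperseg = min(nperseg, x.size)
    noverlap = int(nperseg * overlap)
    freqs, Pxx = sps.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=False,
    )
    return PSDEstimate(
        freqs=freqs,
        Pxx=Pxx,
        n_segments=n_segments,
        window="hamming",
        overlap_fraction=overlap,
    )


def avg_log_psd(psd: PSDEstimate) -> float:
    """Mean of ``10*log10(Pxx)`` over PSD points, in dB.

    Pxx is floored at ``PSD_FLOOR`` so silent bands give a finite
    (very negative) value instead of -inf.
    """
    if psd.P < 1:
        raise InvalidInputError("PSD estimate is empty")
    Pxx = np.maximum(psd.Pxx, PSD_FLOOR)
    return float(np.sum(10.0 * np.log10(Pxx)) / psd.P)


def extract_eeg_features(
    rec: EEGRecording,
    bands: tuple[str, ...] = FEATURE_BANDS,
    denoise_config: DenoiseConfig | None = None,
    denoise: bool = True,
) -> EEGFeatureVector:
    """Full per-trial feature extraction.

    Per channel: wavelet denoise, 4-45 Hz bandpass, 5-level band
    decomposition, then Welch PSD and average log-PSD per selected
    band. Features are ordered channel-major, band-minor.
    """
    unknown = set(bands) - set(BAND_NAMES)
    if unknown:
        raise InvalidInputError(f"unknown band names: {sorted(unknown)}")
    values = np.empty(rec.n_channels * len(bands))
    for ci, channel in enumerate(rec.samples):
        x = channel
        if denoise:
            x = prep.denoise_signal(x, rec.fs, denoise_config)
        x = prep.bandpass_4_45(x, rec.fs)
        decomp = {b.band_name: b.band_signal for b in wavelet_band_decompose(x, rec.fs)}
        for bi, band in enumerate(bands):
            psd = welch_psd(decomp[band], rec.fs)
            values[ci * len(bands) + bi] = avg_log_psd(psd)
    return EEGFeatureVector(
        values=values,
        channel_names=list(rec.channel_names),
        band_names=list(bands),
    )
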