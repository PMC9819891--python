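"""EEG denoising and band-limiting.

White-Gaussian denoising by db4 wavelet decomposition with hard
thresholding under the minimax ("extremum") threshold-selection rule

    lambda = sigma * (0.3936 + 0.1829 * log2(E))   for E > 32
    lambda = 0                                     for E <= 32

where ``E`` is the signal length and ``sigma`` the robust noise scale
estimated from the finest detail coefficients as median(|d|) / 0.6745.
A 4.0-45.0 Hz zero-phase Butterworth bandpass removes the delta band
and line-frequency content before feature extraction.
"""

from __future__ import annotations

import logging

import numpy as np
import pywt
from scipy import signal as sps

from emomap.types import DenoiseConfig, EEGRecording, InvalidInputError, ThresholdEstimate

logger = logging.getLogger(__name__)

#: Gaussian consistency constant: median(|X|) = 0.6745 sigma for X ~ N(0, sigma^2).
MAD_SCALE = 0.6745

#: Order of the Butterworth bandpass (applied forward-backward).
BANDPASS_ORDER = 4
BANDPASS_LOW_HZ = 4.0
BANDPASS_HIGH_HZ = 45.0


def estimate_noise_sigma(detail_coeffs: np.ndarray) -> float:
    """Robust noise scale from wavelet detail coefficients.

    Returns ``median(|d|) / 0.6745``, the standard median-absolute-
    deviation estimate of the Gaussian noise standard deviation.
    """
    d = np.asarray(detail_coeffs, dtype=float)
    if d.size == 0:
        raise InvalidInputError("cannot estimate noise from an empty vector")
    return float(np.median(np.abs(d)) / MAD_SCALE)


def minimax_threshold(E: int, sigma: float) -> float:
    """Minimax (extremum) shrinkage threshold for a signal of length ``E``.

    Zero for short signals (E <= 32); otherwise
    ``sigma * (0.3936 + 0.1829 * log2(E))``.
    """
    if E < 1:
        raise InvalidInputError(f"signal length must be positive, got {E}")
    if sigma < 0:
        raise InvalidInputError(f"sigma must be non-negative, got {sigma}")
    if E <= 32:
        return 0.0
    return float(sigma * (0.3936 + 0.1829 * (np.log(E) / np.log(2))))


def hard_threshold(coeffs: np.ndarray, lambda_: float) -> np.ndarray:
    """Hard shrinkage: keep coefficients with ``|w| >= lambda``, zero the rest."""
    if lambda_ < 0:
        raise InvalidInputError(f"threshold must be non-negative, got {lambda_}")
    w = np.asarray(coeffs, dtype=float)
    return np.where(np.abs(w) >= lambda_, w, 0.0)


def estimate_threshold(signal: np.ndarray, config: DenoiseConfig | None = None) -> ThresholdEstimate:
    """Decompose one level and return the minimax threshold estimate."""
    config = config or DenoiseConfig()
    x = np.asarray(signal, dtype=float)
    _, d1 = pywt.dwt(x, config.wavelet_name, mode=config.boundary_mode)
    Mw = float(np.median(np.abs(d1)))
    sigma = estimate_noise_sigma(d1)
    lam = minimax_threshold(x.size, sigma)
    return ThresholdEstimate(lambda_=lam, sigma=sigma, E=x.size, Mw=Mw)


def _resolve_level(n: int, wavelet: str, level: int | str) -> int:
    max_level = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level == "auto-max":
        return max(max_level, 1)
    if level > max(max_level, 1):
        raise InvalidInputError(
            f"level {level} exceeds maximum admissible level {max_level} "
            f"for signal length {n}"
        )
    return int(level)


def denoise_signal(
    signal: np.ndarray, fs: float, config: DenoiseConfig | None = None
) -> np.ndarray:
    """Wavelet-denoise one channel.

    Decomposes with db4 to the configured (default: maximum admissible)
    level, estimates sigma from the level-1 detail coefficients,
    computes one global minimax threshold from the signal length, hard-
    thresholds every detail level (the approximation is untouched) and
    reconstructs. Output length equals input length.
    """
    config = config or DenoiseConfig()
    x = np.asarray(signal, dtype=float)
    if x.size < 2:
        raise InvalidInputError("signal must have at least 2 samples")
    level = _resolve_level(x.size, config.wavelet_name, config.level)
    coeffs = pywt.wavedec(x, config.wavelet_name, mode=config.boundary_mode, level=level)
    # coeffs = [cA_L, cD_L, ..., cD_1]; sigma comes from the finest details.
    sigma = estimate_noise_sigma(coeffs[-1])
    lam = minimax_threshold(x.size, sigma)
    logger.debug(
        "denoise: N=%d level=%d sigma=%.4g lambda=%.4g", x.size, level, sigma, lam
    )
    denoised = [coeffs[0]] + [hard_threshold(c, lam) for c in coeffs[1:]]
    y = pywt.waverec(denoised, config.wavelet_name, mode=config.boundary_mode)
    return y[: x.size]


def bandpass_4_45(signal: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 4.0-45.0 Hz Butterworth bandpass.

    Requires ``fs > 90`` so the 45 Hz edge sits below Nyquist.
    """
    if fs <= 2 * BANDPASS_HIGH_HZ:
        raise InvalidInputError(
            f"sampling rate must exceed {2 * BANDPASS_HIGH_HZ} Hz, got {fs}"
        )
    x = np.asarray(signal, dtype=float)
    sos = sps.butter(
        BANDPASS_ORDER,
        [BANDPASS_LOW_HZ, BANDPASS_HIGH_HZ],
        btype="bandpass",
        fs=fs,
        output="sos",
    )
    return sps.sosfiltfilt(sos, x)


def preprocess_signal(
    signal: np.ndarray, fs: float, config: DenoiseConfig | None = None
) -> np.ndarray:
    """The module's full preprocessing chain: denoise, then 4-45 Hz bandpass."""
    return bandpass_4_45(denoise_signal(signal, fs, config), fs)


def denoise_recording(rec: EEGRecording, config: DenoiseConfig | None = None) -> EEGRecording:
    """Apply :func:`denoise_signal` to every channel of a recording."""
    cleaned = np.vstack([denoise_signal(ch, rec.fs, config) for ch in rec.samples])
    return EEGRecording(
        channel_names=list(rec.channel_names),
        samples=cleaned,
        fs=rec.fs,
        trial_id=rec.trial_id,
        subject_id=rec.subject_id,
    )
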