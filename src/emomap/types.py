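"""Shared domain types.

Dataclasses for EEG recordings, PSD estimates, audio clips, feature
tables and transition records. Validation happens in ``__post_init__``
so invalid objects cannot be constructed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Closed vocabulary of music emotion classes.
MUSIC_EMOTIONS: tuple[str, ...] = (
    "anger",
    "confidence",
    "disgust",
    "fear",
    "joy",
    "passion",
    "relaxation",
    "sadness",
)

#: The four quadrants of the valence-arousal plane.
QUADRANTS: tuple[str, ...] = ("HVHA", "HVLA", "LVHA", "LVLA")


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


@dataclass
class EEGRecording:
    """A multichannel EEG trial: channels x samples, in microvolts.

    Channel names follow the 10-20 scalp-electrode convention and must
    be unique; all channels share the same length.
    """

    channel_names: list[str]
    samples: np.ndarray
    fs: float
    trial_id: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2:
            raise InvalidInputError(
                f"samples must be channels x N, got shape {self.samples.shape}"
            )
        if self.samples.shape[1] < 1:
            raise InvalidInputError("each channel needs at least one sample")
        if len(self.channel_names) != self.samples.shape[0]:
            raise InvalidInputError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} rows"
            )
        dupes = {n for n in self.channel_names if self.channel_names.count(n) > 1}
        if dupes:
            raise InvalidInputError(f"duplicate channel names: {sorted(dupes)}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class DenoiseConfig:
    """Wavelet-denoising configuration.

    ``level`` may be an explicit positive integer or ``"auto-max"``, in
    which case the maximum admissible decomposition level for the
    signal length and wavelet filter is used.
    """

    wavelet_name: str = "db4"
    threshold_rule: str = "minimax_extremum"
    level: int | str = "auto-max"
    #: Signal-extension mode at the boundaries of the wavelet transform.
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.threshold_rule != "minimax_extremum":
            raise InvalidInputError(
                f"unknown threshold rule {self.threshold_rule!r}"
            )
        if self.level != "auto-max":
            if not isinstance(self.level, int) or self.level < 1:
                raise InvalidInputError(
                    f"level must be a positive integer or 'auto-max', got {self.level!r}"
                )


@dataclass
class ThresholdEstimate:
    """A denoising threshold and the quantities that produced it."""

    lambda_: float
    sigma: float
    E: int
    Mw: float

    def __post_init__(self) -> None:
        if self.lambda_ < 0 or self.sigma < 0 or self.E < 1:
            raise InvalidInputError("threshold estimate out of range")


@dataclass
class SubbandScheme:
    """Dyadic sub-band partition of [1, fs/2] into the five EEG bands."""

    fs: float
    #: (band name, decomposition level label, f_low, f_high)
    bands: list[tuple[str, str, float, float]]


@dataclass
class BandDecomposition:
    """One band-limited component of a signal.

    ``band_signal`` is reconstructed from that band's wavelet
    coefficients alone; summing all five components reproduces the
    input (perfect reconstruction).
    """

    band_name: str
    level_label: str
    band_signal: np.ndarray


@dataclass
class PSDEstimate:
    """Welch periodogram estimate with its estimation parameters."""

    freqs: np.ndarray
    Pxx: np.ndarray
    n_segments: int = 8
    window: str = "hamming"
    overlap_fraction: float = 0.5

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.Pxx = np.asarray(self.Pxx, dtype=float)
        if self.freqs.shape != self.Pxx.shape:
            raise InvalidInputError("freqs and Pxx must have equal length")
        if np.any(self.Pxx < 0):
            raise InvalidInputError("PSD values must be non-negative")

    @property
    def P(self) -> int:
        """Number of PSD points."""
        return int(self.Pxx.size)


@dataclass
class EEGFeatureVector:
    """Per-trial average log-PSD features, channel-major, band-minor.

    ``values[i * n_bands + j]`` is the feature of channel ``i`` in band
    ``j`` (band order as given in ``band_names``), in dB.
    """

    values: np.ndarray
    channel_names: list[str]
    band_names: list[str]
    units: str = "dB"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = len(self.channel_names) * len(self.band_names)
        if self.values.size != expected:
            raise InvalidInputError(
                f"feature vector length {self.values.size} != "
                f"{len(self.channel_names)} channels x {len(self.band_names)} bands"
            )

    def feature_names(self) -> list[str]:
        return [
            f"{ch}_{band}" for ch in self.channel_names for band in self.band_names
        ]


@dataclass
class AudioClip:
    """A fixed-length mono audio clip with samples in [-1, 1]."""

    samples: np.ndarray
    fs: int = 44100
    source_id: str = ""
    clip_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidInputError("clip must be mono (1-D)")
        if self.fs <= 0:
            raise InvalidInputError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


#: Canonical order of the 21 per-clip music features.
MUSIC_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"mfcc_{i}" for i in range(1, 14)]
    + [
        "spectral_centroid",
        "spectral_flux",
        "zero_crossings",
        "rms",
        "bpm",
        "bpm_intensity",
        "mode",
        "roughness",
    ]
)


@dataclass
class MusicFeatureVector:
    """The 21-dimensional per-clip audio feature vector.

    13 mel-cepstral coefficients plus spectral centroid, spectral flux,
    zero-crossing count, RMS level, tempo (BPM), pulse clarity, a
    signed major/minor mode score and sensory roughness.
    """

    values: np.ndarray
    names: tuple[str, ...] = MUSIC_FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != 21:
            raise InvalidInputError(
                f"music feature vector must have 21 values, got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("music feature vector contains NaN/Inf")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class FeatureTable:
    """Instances x features with labels, the unit the classifier consumes."""

    ids: list[str]
    X: np.ndarray
    feature_names: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise InvalidInputError("feature matrix must be 2-D")
        if self.X.shape[0] != len(self.ids) or self.X.shape[0] != len(self.labels):
            raise InvalidInputError("ids, rows and labels must align")
        if self.X.shape[1] != len(self.feature_names):
            raise InvalidInputError("feature names must match matrix columns")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class SVMConfig:
    """RBF-kernel SVM grid-search configuration."""

    C_grid: Sequence[float] = tuple(2.0**k for k in range(-5, 16, 2))
    gamma_grid: Sequence[float] = tuple(2.0**k for k in range(-15, 4, 2))
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise InvalidInputError("need at least 2 folds")
        if not self.C_grid or not self.gamma_grid:
            raise InvalidInputError("parameter grids must be non-empty")


@dataclass
class CVResult:
    """Cross-validation outcome at the best grid point."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    max_accuracy: float
    best_C: float
    best_gamma: float
    confusion: np.ndarray
    class_names: list[str]

    @property
    def confusion_normalized(self) -> np.ndarray:
        row_sums = self.confusion.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(row_sums > 0, self.confusion / row_sums, 0.0)
        return norm


@dataclass
class ChannelRanking:
    """Channels ordered by descending single-channel accuracy."""

    channels: list[str]
    accuracies: list[float]


@dataclass
class VARating:
    """A self-rating on the 1-9 valence and arousal scales."""

    valence: float
    arousal: float

    def __post_init__(self) -> None:
        if not (1 <= self.valence <= 9 and 1 <= self.arousal <= 9):
            raise InvalidInputError(
                f"valence/arousal must lie in [1, 9], got "
                f"({self.valence}, {self.arousal})"
            )


@dataclass(frozen=True)
class TransitionRecord:
    """One observed emotion transition: before state, music type, after state."""

    before: str
    music_type: str
    after: str


@dataclass
class TransitionTable:
    """Conditional before -> after emotion probabilities per music type.

    ``cells[(before, music_type)][after] = (count, probability)``;
    probabilities within each conditioning key sum to 1.
    """

    cells: dict[tuple[str, str], dict[str, tuple[int, float]]]
    granularity: str = "emotion"

    def probability(self, before: str, music_type: str, after: str) -> float:
        return self.cells.get((before, music_type), {}).get(after, (0, 0.0))[1]

    def count(self, before: str, music_type: str, after: str) -> int:
        return self.cells.get((before, music_type), {}).get(after, (0, 0.0))[0]
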