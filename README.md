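# emomap

EEG and music emotion analysis for music-therapy research: recognize a
listener's emotional state from multichannel EEG, classify the emotional
character of music from its audio signal, and map how music of a given
emotional type moves listeners between emotional states.

The package is aimed at researchers studying affective responses to music
who want a fully testable, seedable reimplementation of this kind of
pipeline — every stage runs end-to-end on synthetic EEG, synthetic audio
and synthetic transition records with known ground truth, so no external
datasets are required.

## What it computes

**EEG emotion recognition (EER).** Raw EEG (channels × samples, e.g. 32
channels at 128 Hz) is denoised with a db4 discrete wavelet transform and
hard thresholding under the minimax ("extremum") threshold rule

  λ = ∂ · (0.3936 + 0.1829 · log₂ E)  for E > 32,  λ = 0 otherwise,

where E is the signal length and ∂ = median(|w|)/0.6745 is the robust
noise scale from the finest detail coefficients w. After a zero-phase
4.0–45.0 Hz bandpass, a 4-level db4 decomposition splits each channel into
the five canonical bands (at 128 Hz: δ 1–4, θ 4–8, α 8–16, β 16–32,
γ 32–64 Hz); for each of θ, α, β, γ the feature is the average log power
spectral density

  AvgPSD = (1/P) Σᵢ 10·log₁₀(Pxxᵢ)  [dB]

of the band-reconstructed signal, with Pxx estimated by Welch's averaged
periodogram (Hamming window, ~8 segments, 50% overlap). An RBF-kernel SVM
with grid-searched (C, γ) and stratified 10-fold cross-validation
classifies the channel-major, band-minor feature vector; per-channel
accuracies rank electrodes so a top-k subset can be selected for portable
acquisition.

**Music emotion classification (MEC).** Stereo audio at 44.1 kHz is merged
to mono, cut into non-overlapping 15-second clips, and each clip is
summarised by a 21-dimensional vector: 13 mel-frequency cepstral
coefficients, spectral centroid, spectral flux, zero-crossing count, RMS
level, tempo (BPM) with pulse clarity, a signed major/minor mode score
from Krumhansl–Kessler key-profile correlation, and Plomp–Levelt sensory
roughness. The same SVM harness classifies clips into eight music
emotions (anger, confidence, disgust, fear, joy, passion, relaxation,
sadness).

**Emotion transition mapping.** A vocabulary of 20 emotions is anchored in
the valence–arousal plane (1–9 scales, HV/LV × HA/LA quadrants split at
5). Before/music/after records are aggregated into conditional tables
P(after | before, music type) at emotion or quadrant granularity, with
long-format exports for parallel-coordinate plots.

## Worked example

```python
import numpy as np
from emomap import synthetic_data as sd, classification as cl, audio_features as af
from emomap.types import SVMConfig

# --- EEG: 4 emotion classes differing in band power, 32 channels ---
spec = sd.EEGSimSpec(n_classes=4, trials_per_class=10, n_channels=8, seed=0)
recordings, labels, truth = sd.simulate_eeg(spec)
table = cl.feature_table_from_recordings(recordings, labels)
result = cl.grid_search_cv(table, SVMConfig(folds=10, seed=1))
print(f"EER CV accuracy: {result.mean_accuracy:.3f} "
      f"(best C={result.best_C}, gamma={result.best_gamma})")

# --- music: one synthetic clip per class, 21-dim features ---
clip = sd.synthesize_clip(sd.DEFAULT_AUDIO_PROFILES["joy"],
                          rng=np.random.default_rng(5))
fv = af.extract_music_features(clip)
d = fv.as_dict()
print(f"joy clip: bpm={d['bpm']:.1f} mode={d['mode']:.2f} "
      f"rms={d['rms']:.3f} centroid={d['spectral_centroid']:.0f} Hz")
```

prints

```
EER CV accuracy: 1.000 (best C=0.03125, gamma=3.0517578125e-05)
joy clip: bpm=140.0 mode=0.08 rms=0.158 centroid=1383 Hz
```

The perfect cross-validated accuracy reflects the 3:1 band-power contrast
the generator plants between classes; the joy clip's tempo matches its
140 BPM profile, the positive mode score its major triad, and the RMS its
configured level. A command-line interface `emomap` exposes the same
pipeline as subcommands (`denoise`, `eeg-features`, `audio-features`,
`train`, `rank-channels`, `transitions`, `synth-eeg`, `synth-audio`,
`synth-transitions`).

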