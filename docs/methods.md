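# Methods

This note documents the models implemented in emomap, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions taken where the design was open.

## EEG preprocessing

**Denoising model.** EEG trials are assumed to carry additive white
Gaussian noise; structured artifacts (eye blinks, muscle activity) are
out of scope. Denoising is wavelet shrinkage: db4 decomposition to the
maximum admissible level for the signal length (overridable via
`DenoiseConfig.level`), hard thresholding of all detail levels with a
single global minimax threshold, untouched approximation, inverse
transform. The threshold is λ = ∂·(0.3936 + 0.1829·log₂E) for signal
length E > 32 and exactly 0 for E ≤ 32, with the noise scale
∂ = median(|d₁|)/0.6745 estimated from the level-1 (finest) detail
coefficients. Three interpretation choices are deliberate:

* the median is taken over *absolute* coefficients — a signed median of
  zero-mean details would be ≈ 0 and make the rule vacuous; dividing by
  0.6745 is the standard Gaussian-consistency constant;
* one global λ is applied to every detail level (per-level thresholds
  would require per-level noise models that nothing here pins down);
* thresholding is hard (coefficients at or above λ are kept verbatim),
  which preserves signal amplitude at the cost of noisier survivors.

Boundary handling uses symmetric extension throughout
(`BOUNDARY_MODE`/`DenoiseConfig.boundary_mode`).

**Measured efficacy and its limits.** On a 10 Hz unit sine at 128 Hz
with 5 dB-SNR Gaussian noise, hard-threshold minimax shrinkage alone
gains ≈ 2.4–2.9 dB across seeds. The limit is structural: the sine's
energy leaks into the D4 and D2 db4 octaves (the 8 and 16 Hz band edges
sit next to 10 Hz), and noise in the signal-carrying D3 octave survives
because the large signal coefficients carry it past the threshold. A
universal-threshold (VisuShrink) hard shrinkage on the same signal gains
≈ 0 dB, so this is a property of wavelet shrinkage on narrowband
signals, not of this implementation. The preprocessing chain as a whole
(denoise followed by the 4.0–45.0 Hz bandpass, `preprocess_signal`)
gains ≈ 3.2 dB averaged over a fixed 8-seed set at these conditions,
which is the figure the acceptance test checks.

**Bandpass.** 4.0–45.0 Hz order-4 Butterworth, applied forward-backward
(zero phase, so effectively order 8). Requires fs > 90 Hz. Measured on
fs = 128: ≤ 1 dB ripple at 10 Hz, > 20 dB attenuation at 1 Hz and at
Nyquist.

## EEG features

A 4-level db4 DWT yields five sub-band components (cA4 + cD4…cD1) that
partition [1, fs/2]: at 128 Hz, δ 1–4, θ 4–8, α 8–16, β 16–32,
γ 32–64 Hz. Each band signal is reconstructed from its coefficient
level alone, so the five components sum to the input exactly. δ is
dropped (sleep-related; also removed by the bandpass), and the nominal
γ band is effectively limited to 32–45 Hz by the bandpass.

Per band, power spectral density is estimated by Welch's method:
Hamming window, window length ⌊2N/9⌋ so eight half-overlapping segments
tile the signal (trailing samples clipped; for lengths not divisible
the segment count may differ by one), no detrending, density scaling.
The feature is the mean of 10·log₁₀(Pxx) over all PSD points, in dB,
with Pxx floored at 1e-12 so silent bands stay finite. Features are
ordered channel-major, band-minor (θ, α, β, γ), giving
n_channels × 4 dimensions.

A property of this mean-log feature worth knowing: it rewards power
*spread* across frequency. A pure tone, however large, lifts only a few
PSD bins and is heavily discounted relative to band-limited broadband
activity of the same total power. This is why the synthetic generator
models band rhythms with finite bandwidth (below) and why
"dominant alpha" demonstrations require the alpha rhythm to stand well
above the background.

## Audio features

All frame-level analysis uses a Hann STFT with 2048-sample frames and
1024 hop at 44.1 kHz, except where a different resolution is required:
onset analysis uses 1024/256 (≈ 172 Hz envelope rate) and chroma uses
8192/4096 (≈ 5.4 Hz bins, needed to separate semitones below ~370 Hz).
Frame quantities aggregate to the clip by averaging over frames; an
implementation that summed instead would scale every value by the frame
count without changing classification after feature scaling.

* **MFCC**: 26 triangular mel filters over 0–fs/2 (HTK mel scale), log
  energies floored at 1e-10, cosine transform
  cₙ = Σₘ E(m)·cos(πn(m−0.5)/M), coefficients 1–13 (c₀ excluded).
* **Spectral centroid**: power-weighted mean frequency pooled over all
  frames; 0 Hz for silence.
* **Spectral flux**: each frame's magnitude spectrum normalized to unit
  sum, squared frame-to-frame differences summed over bins and averaged
  over frame pairs.
* **Zero crossings**: total sign-change count with sign(0) = +1 (a
  count, not a rate, so it scales with clip length).
* **RMS**: root mean square of the samples.
* **Tempo / pulse clarity**: half-wave-rectified spectral-flux onset
  envelope, lightly Hann-smoothed, mean-removed, autocorrelated. Among
  autocorrelation peaks within 90% of the in-range maximum the smallest
  lag wins (guarding against period doubling), parabolic interpolation
  refines the lag, BPM = 60/T restricted to 60–180. Clarity is the peak
  height over the lag-0 value, in [0, 1]; silence reports the range
  midpoint flagged with clarity 0.
* **Mode**: 12-bin chroma (pitch-class-summed spectral power,
  55–4186 Hz) correlated against all 12 rotations of the
  Krumhansl–Kessler major and minor probe-tone profiles; the score is
  best-major minus best-minor correlation, positive for major. The
  score lives in [−2, 2] by construction; other toolchains report mode
  on different scales, so only the sign and relative magnitude are
  comparable.
* **Roughness**: per frame, spectral peaks (at most 16, relative
  threshold 1e-4) contribute pairwise Plomp–Levelt dissonance
  d = a₁a₂·(e^(−3.5sΔf) − e^(−5.75sΔf)), s = 0.24/(0.021·f_min + 19),
  averaged over frames. A 24-band envelope-beating variant exists in
  the literature; the peak-pair form was chosen as the standard
  spectral-domain parameterization.

Clips are exactly 15 s (661,500 samples); the segmenter truncates, so a
59.9 s track yields 3 clips. Stereo is merged by channel mean. The
feature vector is 13 MFCCs + 8 scalars = 21 dimensions in a fixed,
documented order.

## Classification

Features are min-max scaled to [−1, 1] with parameters fitted on
training folds only (constant features map to 0). The classifier is an
RBF-kernel SVM; (C, γ) are grid-searched over the canonical coarse
grids C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} by stratified
10-fold cross-validation (stratification keeps every class in every
fold, which a 20-class problem requires). Fold assignment is seeded;
the same seed and table reproduce the result exactly. Both the mean and
the maximum fold accuracy at the best grid point are reported, along
with the pooled confusion matrix over that grid point's test folds —
pooled-CV accuracies, not held-out-test accuracies, and labelled as
such. Channel ranking sorts per-channel accuracies descending with ties
broken by input order; top-k evaluation rebuilds the feature table from
the k best channels and reruns the full grid search.

## Synthetic data

**EEG.** Each trial is Gaussian noise plus, per band, a comb of
random-phase sinusoids at 0.5 Hz spacing spanning the band (θ 4–8,
α 8–16, β 16–32, γ 32–44 Hz — γ stops inside the bandpass), scaled so
the comb's total RMS equals the profile amplitude. The comb gives each
rhythm finite bandwidth, which real EEG has and the mean-log-PSD
feature expects. Class structure lives exactly where the features look:
by default class k boosts band k at 3:1 over a 1 µV baseline with unit
noise, on all channels (an `informative_channels` subset can restrict
it, which is how channel-ranking recovery is exercised). Defaults:
10 s trials at 128 Hz — long enough for stable Welch estimates at
⌊2N/9⌋-sample windows while keeping a 160-trial, 32-channel study
desk-scale. Not emulated: 1/f background spectra, artifacts, volume
conduction between channels, non-stationarity. Recovery results on
this generator validate the feature chain, not performance on real EEG.

**Music.** Each clip sums a click train (damped 1 kHz bursts) at the
class tempo, a triad (root 220 Hz, major or minor third, fifth, three
harmonics per note), noise with a class-specific spectral tilt
(dB/octave around 1 kHz, 20 Hz highpassed), and optionally a partial
detuned against the fifth to create beating roughness. The clip is
scaled to RMS = 0.2 × level (with a peak guard at 0.99) so the
intensity feature reflects the class profile rather than click density.
The eight default profiles separate every feature family for at least
one class pair: tempos 60–168 BPM at least 5 BPM apart, tilts 0 to
−6 dB/oct, four major / four minor classes, detunings 0–30 Hz, levels
0.55–0.85. Not emulated: melody, vocals, production effects, tempo
drift — so classification here validates the extractors, not
performance on real recordings.

**Transitions.** Records are drawn i.i.d. from a known conditional
matrix P(after | before, music type), conditioning keys uniform. The
default matrix uses two conditioning keys so that a 5000-record draw
pins every cell to within ±0.03 with high probability (per-key n ≈
2500 gives a binomial standard error ≤ 0.01 per cell).

## Emotion anchors

The 20-emotion vocabulary (intimacy, surprise, tiredness, anxiety,
concentration, pain, relaxation, confidence, disgust, insecurity, fear,
despair, hope, gratitude, anger, passion, sadness, mania, joy, trust)
ships with approximate valence–arousal coordinates on the 1–9 scale in
`emomap/data/emotion_anchors.json`. The coordinates encode quadrant
membership and qualitative neighbourhoods (intimacy and surprise are
near neighbours, which is why they confuse; sadness and despair sit
deep in LVLA) — they are an editable configuration default, not
measured ground truth, and every function accepts a custom anchor set.
Ratings at the 5.0 threshold count as High in quadrant assignment;
nearest-anchor annotation breaks exact ties lexicographically.

## Known limitations

* Denoising gains are modest for narrowband signals near db4 band
  edges (see above); the rule is kept as specified rather than tuned.
* The Welch "eight segments" convention yields seven to nine segments
  for lengths far from divisibility; the window-length rule, not the
  segment count, is the contract.
* Mode and roughness scales are implementation-specific; compare signs
  and orderings, not magnitudes, across toolchains.
* BPM search is bounded to 60–180; genuinely slower/faster material
  aliases to a multiple inside the range.
* All validation is on synthetic data; headline accuracies on public
  EEG corpora are outside what this package can or does claim.
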