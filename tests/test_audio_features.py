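"""Music feature extraction: closed-form checks and oracle equivalences."""

import numpy as np
import pytest

from emomap import audio_features as af
from emomap.types import AudioClip, InvalidInputError

from conftest import FS, SEMITONE, make_click_track, make_tone, make_triad


class TestMergeAndSegment:
    def test_identical_channels_pass_through(self, rng):
        x = rng.normal(size=1000)
        np.testing.assert_array_equal(af.merge_stereo(x, x), x)

    def test_antiphase_cancels(self, rng):
        x = rng.normal(size=1000)
        np.testing.assert_array_equal(af.merge_stereo(x, -x), np.zeros(1000))

    def test_matches_mean_oracle(self, rng):
        left, right = rng.normal(size=(2, 777))
        np.testing.assert_array_equal(af.merge_stereo(left, right), (left + right) / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            af.merge_stereo(np.ones(3), np.ones(4))

    @pytest.mark.parametrize(
        "seconds,expected", [(60.0, 4), (59.9, 3), (14.0, 0), (45.0, 3)]
    )
    def test_clip_count_truncates(self, seconds, expected):
        mono = np.zeros(int(FS * seconds))
        clips = af.segment_clips(mono, FS)
        assert len(clips) == expected

    def test_clips_disjoint_ordered_and_within_input(self, rng):
        mono = rng.normal(size=int(FS * 38))
        clips = af.segment_clips(mono, FS)
        total = sum(c.samples.size for c in clips)
        assert total <= mono.size
        for i, c in enumerate(clips):
            assert c.clip_index == i
            np.testing.assert_array_equal(
                c.samples, mono[i * FS * 15 : (i + 1) * FS * 15]
            )


class TestSpectralShape:
    @pytest.mark.parametrize("freq,tol", [(1000.0, 20.0), (5000.0, 50.0)])
    def test_pure_tone_centroid(self, freq, tol):
        clip = make_tone(freq, duration=2.0)
        assert af.spectral_centroid(clip) == pytest.approx(freq, abs=tol)

    def test_two_tone_centroid_is_weighted_mean(self):
        t = np.arange(int(FS * 2)) / FS
        x = 0.4 * np.sin(2 * np.pi * 400 * t) + 0.4 * np.sin(2 * np.pi * 1200 * t)
        assert af.spectral_centroid(AudioClip(samples=x, fs=FS)) == pytest.approx(800, abs=30)

    def test_silent_clip_centroid_zero(self):
        assert af.spectral_centroid(AudioClip(samples=np.zeros(FS), fs=FS)) == 0.0

    def test_flux_zero_for_stationary_frames(self):
        assert af.spectral_flux(make_tone(1000, duration=2.0)) < 1e-8

    def test_flux_positive_for_alternating_content(self):
        frame = af.FRAME_LENGTH
        x = np.concatenate(
            [np.sin(2 * np.pi * 800 * np.arange(frame) / FS), np.zeros(frame)] * 8
        )
        assert af.spectral_flux(AudioClip(samples=x, fs=FS)) > 0

    def test_flux_matches_frame_pair_oracle(self, rng):
        clip = AudioClip(samples=rng.normal(size=FS // 2) * 0.1, fs=FS)
        frames = af.stft_magnitudes(clip)
        norm = frames.magnitudes / frames.magnitudes.sum(axis=1, keepdims=True)
        oracle = np.mean(
            [np.sum((norm[i] - norm[i - 1]) ** 2) for i in range(1, norm.shape[0])]
        )
        assert af.spectral_flux(clip) == pytest.approx(oracle, abs=1e-10)

    def test_flux_needs_two_frames(self):
        with pytest.raises(InvalidInputError):
            af.spectral_flux(AudioClip(samples=np.zeros(af.FRAME_LENGTH), fs=FS))


class TestTemporalFeatures:
    def test_alternating_signs_hand_count(self):
        clip = AudioClip(samples=np.array([1.0, -1.0, 1.0, -1.0]), fs=FS)
        assert af.zero_crossings(clip) == 3

    def test_constant_signal_no_crossings(self):
        clip = AudioClip(samples=np.full(100, 0.3), fs=FS)
        assert af.zero_crossings(clip) == 0

    @pytest.mark.parametrize("freq", [5.0, 50.0, 440.0])
    def test_sine_crossing_count(self, freq):
        clip = make_tone(freq, duration=2.0, amp=1.0)
        assert abs(af.zero_crossings(clip) - 2 * freq * 2.0) <= 2

    def test_crossings_bounded_by_length(self, rng):
        clip = AudioClip(samples=rng.normal(size=500), fs=FS)
        assert 0 <= af.zero_crossings(clip) <= 499

    def test_rms_constant(self):
        assert af.rms(AudioClip(samples=np.full(64, 0.5), fs=FS)) == 0.5

    def test_rms_zeros(self):
        assert af.rms(AudioClip(samples=np.zeros(64), fs=FS)) == 0.0

    def test_rms_unit_sine(self):
        clip = make_tone(100.0, duration=1.0, amp=1.0)  # whole periods
        assert af.rms(clip) == pytest.approx(1 / np.sqrt(2), abs=1e-3)


class TestRhythm:
    @pytest.mark.parametrize("bpm", [60, 90, 120, 150, 180])
    def test_click_track_recovery(self, bpm):
        est, clarity = af.estimate_bpm(make_click_track(bpm))
        assert est == pytest.approx(bpm, abs=2.0)
        assert clarity > 0.5

    def test_noise_has_lower_pulse_clarity_than_clicks(self, rng):
        _, clarity_clicks = af.estimate_bpm(make_click_track(120))
        noise = AudioClip(samples=0.3 * rng.normal(size=FS * 15), fs=FS)
        _, clarity_noise = af.estimate_bpm(noise)
        assert clarity_noise < clarity_clicks

    def test_silent_clip_flagged(self):
        bpm, clarity = af.estimate_bpm(AudioClip(samples=np.zeros(FS * 2), fs=FS))
        assert clarity == 0.0
        assert bpm == pytest.approx((af.BPM_MIN + af.BPM_MAX) / 2)


class TestMode:
    @pytest.mark.parametrize("semitone_offset", range(12))
    def test_sign_correct_for_major_and_minor_triads(self, semitone_offset):
        root = 261.63 * SEMITONE**semitone_offset
        assert af.estimate_mode(make_triad(root, minor=False, duration=3.0)) > 0
        assert af.estimate_mode(make_triad(root, minor=True, duration=3.0)) < 0

    def test_noise_score_smaller_than_triads(self, rng):
        noise = AudioClip(samples=0.3 * rng.normal(size=FS * 3), fs=FS)
        score_noise = abs(af.estimate_mode(noise))
        score_major = abs(af.estimate_mode(make_triad(261.63, duration=3.0)))
        score_minor = abs(af.estimate_mode(make_triad(220.0, minor=True, duration=3.0)))
        assert score_noise < score_major
        assert score_noise < score_minor

    def test_silence_scores_zero(self):
        assert af.estimate_mode(AudioClip(samples=np.zeros(FS), fs=FS)) == 0.0


class TestRoughness:
    def test_beating_pair_rougher_than_octave(self):
        t = np.arange(FS * 2) / FS

        def pair(f2):
            x = 0.4 * np.sin(2 * np.pi * 440 * t) + 0.4 * np.sin(2 * np.pi * f2 * t)
            return AudioClip(samples=x, fs=FS)

        assert af.roughness(pair(460)) > af.roughness(pair(880))

    def test_pure_tone_nearly_smooth(self):
        t = np.arange(FS * 2) / FS
        beat = AudioClip(
            samples=0.4 * np.sin(2 * np.pi * 440 * t) + 0.4 * np.sin(2 * np.pi * 460 * t),
            fs=FS,
        )
        tone = make_tone(440.0, duration=2.0)
        assert af.roughness(tone) < 0.01 * af.roughness(beat)

    def test_silence_is_zero(self):
        assert af.roughness(AudioClip(samples=np.zeros(FS), fs=FS)) == 0.0


class TestMFCC:
    def test_silence_is_finite(self):
        coeffs = af.mfcc(AudioClip(samples=np.zeros(FS), fs=FS))
        assert coeffs.shape == (13,)
        assert np.all(np.isfinite(coeffs))

    def test_deterministic(self, rng):
        clip = AudioClip(samples=0.2 * rng.normal(size=FS), fs=FS)
        np.testing.assert_array_equal(af.mfcc(clip), af.mfcc(clip))

    def test_matches_brute_force_cepstrum_oracle(self, rng):
        """Independent per-frame double-loop mel-cepstrum on white noise."""
        clip = AudioClip(samples=0.3 * rng.normal(size=FS // 4), fs=FS)
        L, M = 13, 26
        n_fft, hop = af.FRAME_LENGTH, af.HOP_LENGTH
        fb = af.mel_filterbank(M, n_fft, FS)
        window = np.hanning(n_fft)
        x = clip.samples
        frames = []
        start = 0
        while start + n_fft <= x.size:
            power = np.abs(np.fft.rfft(x[start : start + n_fft] * window)) ** 2
            log_e = [
                np.log(max(np.dot(fb[m], power), af.LOG_ENERGY_FLOOR)) for m in range(M)
            ]
            coeffs = []
            for n in range(1, L + 1):
                acc = 0.0
                for m in range(1, M + 1):
                    acc += log_e[m - 1] * np.cos(np.pi * n * (m - 0.5) / M)
                coeffs.append(acc)
            frames.append(coeffs)
            start += hop
        oracle = np.mean(frames, axis=0)
        np.testing.assert_allclose(af.mfcc(clip), oracle, atol=1e-8)


class TestFeatureVector:
    def test_twenty_one_values_in_documented_order(self, rng):
        clip = AudioClip(samples=0.2 * rng.normal(size=FS * 2), fs=FS)
        fv = af.extract_music_features(clip)
        assert fv.values.size == 21
        assert fv.names[:2] == ("mfcc_1", "mfcc_2")
        assert fv.names[-1] == "roughness"

    def test_identical_clips_identical_vectors(self, rng):
        clip = AudioClip(samples=0.2 * rng.normal(size=FS * 2), fs=FS)
        np.testing.assert_array_equal(
            af.extract_music_features(clip).values,
            af.extract_music_features(clip).values,
        )

    def test_tempo_change_leaves_rms_close(self):
        from emomap.synthetic_data import AudioClassProfile, synthesize_clip

        base = dict(tilt_db_per_octave=-2.0, mode="major", detune_hz=0.0, level=0.8)
        slow = synthesize_clip(
            AudioClassProfile(tempo_bpm=80.0, **base), rng=np.random.default_rng(0)
        )
        fast = synthesize_clip(
            AudioClassProfile(tempo_bpm=160.0, **base), rng=np.random.default_rng(0)
        )
        fv_slow = af.extract_music_features(slow)
        fv_fast = af.extract_music_features(fast)
        assert fv_slow["bpm"] != pytest.approx(fv_fast["bpm"], abs=2.0)
        assert fv_slow["rms"] == pytest.approx(fv_fast["rms"], rel=0.05)
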