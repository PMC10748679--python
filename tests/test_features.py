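"""Acoustic feature extraction: perturbation measures, tracking, segmentation."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from speechassay.audio import AudioSample
from speechassay.features import (
    FEATURE_NAMES,
    REFERENCE_NAMES,
    ddk_measures,
    extract_features,
    extract_reference_features,
    hnr_measures,
    intensity_measures,
    jitter_measures,
    segment_speech_pause,
    shimmer_measures,
    timing_measures,
    track_f0,
    zcr_measures,
)
from speechassay.features.segmentation import SegmentationResult
from speechassay.synth import DDKSpec, VoiceSpec, synth_ddk, synth_vowel

FS = 44100


def _pulse_train_audio(f0=100.0, dur=1.0, fs=FS):
    n = int(dur * fs)
    x = np.zeros(n)
    period = int(round(fs / f0))
    x[::period] = 0.8
    return AudioSample(x, fs)


class TestTrackF0:
    def test_pulse_train_mean_f0(self):
        cyc = track_f0(_pulse_train_audio(100.0))
        f0 = cyc.frame_f0_hz[np.isfinite(cyc.frame_f0_hz)]
        assert np.mean(f0) == pytest.approx(100.0, abs=1.0)

    def test_white_noise_mostly_unvoiced(self):
        rng = np.random.default_rng(0)
        audio = AudioSample(np.clip(rng.normal(0, 0.2, FS), -1, 1), FS)
        cyc = track_f0(audio)
        assert cyc.voiced_mask.mean() < 0.10

    def test_vowel_median_f0_matches_sidecar(self, vowel_perturbed):
        audio, side = vowel_perturbed
        cyc = track_f0(audio)
        truth = 1.0 / np.mean(side.periods_s)
        f0 = cyc.frame_f0_hz[np.isfinite(cyc.frame_f0_hz)]
        assert np.median(f0) == pytest.approx(truth, abs=2.0)

    def test_silence_gives_empty_series(self):
        cyc = track_f0(AudioSample(np.zeros(FS // 2), FS))
        assert cyc.n_cycles == 0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            track_f0(_pulse_train_audio(), floor_hz=500, ceiling_hz=60)


class TestJitter:
    def test_constant_periods_all_zero(self):
        out = jitter_measures(np.full(50, 0.01))
        for key in ("local", "local_abs", "rap", "ppq5", "ddp"):
            assert out[key] == 0.0

    def test_alternating_periods_local(self):
        periods = np.tile([0.010, 0.011], 25)
        out = jitter_measures(periods)
        assert out["local"] == pytest.approx(0.001 / 0.0105 * 100.0, rel=1e-6)
        assert out["local_abs"] == pytest.approx(0.001, rel=1e-6)

    def test_ddp_is_three_rap(self):
        rng = np.random.default_rng(4)
        periods = 0.01 + 0.0005 * rng.standard_normal(60)
        out = jitter_measures(periods)
        assert out["ddp"] == pytest.approx(3.0 * out["rap"], rel=1e-12)

    def test_too_few_cycles_nan_with_warning(self):
        with pytest.warns(UserWarning, match="jitter undefined"):
            out = jitter_measures(np.full(4, 0.01))
        assert all(np.isnan(v) for v in out.values())

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.002, 0.02), min_size=6, max_size=60))
    def test_matches_direct_formula(self, raw):
        """Module output equals independent formula evaluation to 1e-9."""
        periods = np.asarray(raw)
        out = jitter_measures(periods)
        mean_t = periods.mean()
        local = np.mean(np.abs(np.diff(periods))) / mean_t * 100
        rap = np.mean(
            [abs(periods[i] - periods[i - 1 : i + 2].mean()) for i in range(1, len(periods) - 1)]
        ) / mean_t * 100
        assert out["local"] == pytest.approx(local, rel=1e-9, abs=1e-12)
        assert out["rap"] == pytest.approx(rap, rel=1e-9, abs=1e-12)


class TestShimmer:
    def test_constant_amplitudes_all_zero(self):
        out = shimmer_measures(np.full(50, 0.5))
        assert all(v == 0.0 for v in out.values())

    def test_alternating_amplitudes_local_db(self):
        amps = np.tile([1.0, 0.9], 25)
        out = shimmer_measures(amps)
        assert out["local_db"] == pytest.approx(abs(20 * np.log10(0.9)), rel=1e-9)

    def test_dda_is_three_apq3(self):
        rng = np.random.default_rng(5)
        amps = 1.0 + 0.05 * rng.standard_normal(40)
        out = shimmer_measures(amps)
        assert out["dda"] == pytest.approx(3.0 * out["apq3"], rel=1e-12)

    def test_apq11_needs_twelve_cycles(self):
        amps = 1.0 + 0.05 * np.random.default_rng(6).standard_normal(10)
        out = shimmer_measures(amps)
        assert np.isnan(out["apq11"])
        assert np.isfinite(out["local"])

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.1, 1.0), min_size=12, max_size=60))
    def test_matches_direct_formula(self, raw):
        amps = np.asarray(raw)
        out = shimmer_measures(amps)
        local = np.mean(np.abs(np.diff(amps))) / amps.mean() * 100
        apq3 = np.mean(
            [abs(amps[i] - amps[i - 1 : i + 2].mean()) for i in range(1, len(amps) - 1)]
        ) / amps.mean() * 100
        assert out["local"] == pytest.approx(local, rel=1e-9, abs=1e-12)
        assert out["apq3"] == pytest.approx(apq3, rel=1e-9, abs=1e-12)


class TestHNR:
    def test_noiseless_harmonic_is_high(self, vowel_clean):
        audio, _ = vowel_clean
        out = hnr_measures(audio, track_f0(audio), "ac")
        assert out["mean"] >= 40.0

    def test_planted_hnr_recovered_within_2db(self, vowel_hnr10):
        audio, side = vowel_hnr10
        out = hnr_measures(audio, track_f0(audio), "ac")
        assert out["mean"] == pytest.approx(side.hnr_db_true(), abs=2.0)

    def test_unknown_method_rejected(self, vowel_clean):
        audio, _ = vowel_clean
        with pytest.raises(ValueError):
            hnr_measures(audio, track_f0(audio), "xx")

    def test_unvoiced_input_nan(self):
        audio = AudioSample(np.zeros(FS // 2), FS)
        out = hnr_measures(audio, track_f0(audio), "cc")
        assert np.isnan(out["mean"])


class TestIntensity:
    def test_constant_tone_zero_spread(self):
        t = np.arange(FS) / FS
        audio = AudioSample(0.5 * np.sin(2 * np.pi * 220 * t), FS)
        out = intensity_measures(audio)
        assert out["var"] < 0.01 and out["range"] < 0.1

    def test_doubling_amplitude_adds_6db_and_quadruples_energy(self):
        rng = np.random.default_rng(7)
        x = 0.1 * np.clip(rng.normal(0, 1, FS), -3, 3)  # headroom: no clipping at 2x
        a1 = intensity_measures(AudioSample(np.clip(x, -1, 1), FS))
        a2 = intensity_measures(AudioSample(np.clip(2 * x, -1, 1), FS))
        assert a2["mean_db"] - a1["mean_db"] == pytest.approx(6.02, abs=0.05)
        assert a2["mean_energy"] / a1["mean_energy"] == pytest.approx(4.0, rel=0.01)

    def test_digital_silence_reported_at_floor(self):
        out = intensity_measures(AudioSample(np.zeros(FS // 2), FS))
        assert out["mean_db"] == -120.0


class TestZCR:
    def test_sine_two_crossings_per_cycle(self):
        # 101.3 Hz keeps frame phases incommensurate with the 10 ms hop
        t = np.arange(FS) / FS
        audio = AudioSample(0.5 * np.sin(2 * np.pi * 101.3 * t), FS)
        assert zcr_measures(audio)["mean"] == pytest.approx(2 * 101.3, abs=5.0)

    def test_white_noise_half_sample_rate(self):
        rng = np.random.default_rng(8)
        audio = AudioSample(np.clip(rng.normal(0, 0.2, 2 * FS), -1, 1), FS)
        assert zcr_measures(audio)["mean"] == pytest.approx(FS / 2, rel=0.05)

    def test_constant_signal_zero(self):
        audio = AudioSample(np.full(FS // 2, 0.3), FS)
        assert zcr_measures(audio)["mean"] == 0.0


class TestSegmentation:
    def test_planted_pauses_counted_and_classed(self, passage_three_pauses):
        audio, side, _ = passage_three_pauses
        seg = segment_speech_pause(audio)
        classes = [c for _, _, c in seg.pauses]
        assert classes == ["short", "medium", "long"]
        durs = [e - s for s, e, _ in seg.pauses]
        truth = [b - a for a, b in side.pause_bounds_s]
        np.testing.assert_allclose(durs, truth, atol=0.030)

    def test_continuous_tone_no_pauses(self):
        t = np.arange(2 * FS) / FS
        audio = AudioSample(0.5 * np.sin(2 * np.pi * 220 * t), FS)
        seg = segment_speech_pause(audio)
        assert len(seg.pauses) == 0
        assert seg.phonated_time_s / seg.total_time_s > 0.97

    def test_all_silence_no_segments(self):
        seg = segment_speech_pause(AudioSample(np.zeros(FS), FS))
        assert seg.speech_segments == [] and seg.pauses == []


class TestTiming:
    def test_speech_rate_arithmetic(self):
        seg = SegmentationResult([(0.0, 40.0)], [], 40.0, 40.0)
        out = timing_measures(seg, {"n_words": 99})
        assert out["speech_rate"] == pytest.approx(148.5)
        assert out["articulation_rate"] == pytest.approx(out["speech_rate"])

    def test_pauses_separate_rates(self):
        seg = SegmentationResult([(0, 30.0)], [(30.0, 40.0, "long")], 30.0, 40.0)
        out = timing_measures(seg, {"n_words": 99})
        assert out["articulation_rate"] > out["speech_rate"]
        assert out["pause_word_ratio"] == pytest.approx(10 / 30)

    def test_no_transcript_gives_nan_word_rates(self):
        seg = SegmentationResult([(0.0, 10.0)], [], 10.0, 10.0)
        out = timing_measures(seg, None)
        assert np.isnan(out["speech_rate"])
        assert out["phonation_rate"] == pytest.approx(1.0)


class TestDDKMeasures:
    def test_regular_rate_and_ctv(self, ddk_regular):
        audio, _ = ddk_regular
        out = ddk_measures(audio)
        assert out["rate"] == pytest.approx(5.0, abs=0.2)
        assert out["ctv"] < 0.005

    def test_planted_ctv_recovered(self):
        audio, side = synth_ddk(DDKSpec(rate_syll_per_s=4.0, ctv_s=0.03, n_syll=20, seed=2))
        truth = np.std(np.diff(side.syllable_onsets_s), ddof=1)
        out = ddk_measures(audio)
        assert out["ctv"] == pytest.approx(truth, abs=0.010)

    def test_single_burst_undefined(self):
        x = np.zeros(FS)
        x[1000:3000] = 0.5
        out = ddk_measures(AudioSample(x, FS))
        assert np.isnan(out["rate"]) and np.isnan(out["ctv"])


class TestExtract:
    def test_exactly_53_named_values(self, vowel_perturbed):
        vec = extract_features(vowel_perturbed[0], "phonation")
        assert list(vec.index) == list(FEATURE_NAMES)
        assert len(vec) == 53

    def test_phonation_has_no_pauses_and_full_phonation(self, vowel_clean):
        vec = extract_features(vowel_clean[0], "phonation")
        assert vec["short pause ct norm"] == 0.0
        assert vec["long pause ct norm"] == 0.0
        assert vec["phonation rate"] == pytest.approx(1.0, abs=0.03)

    def test_deterministic(self, vowel_perturbed):
        v1 = extract_features(vowel_perturbed[0], "phonation")
        v2 = extract_features(vowel_perturbed[0], "phonation")
        assert v1.equals(v2)

    def test_clean_vowel_perturbation_floors(self, vowel_clean):
        vec = extract_features(vowel_clean[0], "phonation")
        assert vec["jitter local"] < 0.1
        assert vec["shimmer local"] < 0.5

    def test_scale_invariance(self, vowel_perturbed):
        audio, _ = vowel_perturbed
        half = AudioSample(audio.samples * 0.5, audio.fs_hz, task="phonation")
        v1 = extract_features(audio, "phonation")
        v2 = extract_features(half, "phonation")
        for name in ("jitter local", "shimmer local", "F0 mean", "ZCR mean",
                     "HNR ac mean", "phonation rate"):
            assert v2[name] == pytest.approx(v1[name], rel=0.02), name
        assert v1["int mean dB"] - v2["int mean dB"] == pytest.approx(6.02, abs=0.1)

    def test_time_reversal_stability(self, vowel_perturbed):
        audio, _ = vowel_perturbed
        rev = AudioSample(audio.samples[::-1].copy(), audio.fs_hz, task="phonation")
        v1 = extract_features(audio, "phonation")
        v2 = extract_features(rev, "phonation")
        for name in ("F0 mean", "int mean dB", "ZCR mean"):
            assert v2[name] == pytest.approx(v1[name], rel=0.02), name


class TestReferenceExtractor:
    def test_reference_set_sizes(self, vowel_clean, ddk_regular, passage_three_pauses):
        assert len(extract_reference_features(vowel_clean[0], "phonation")) == 43
        assert len(extract_reference_features(ddk_regular[0], "ddk")) == 2
        vec = extract_reference_features(
            passage_three_pauses[0], "passage", passage_three_pauses[2]
        )
        assert len(vec) == 80
        assert list(vec.index) == list(REFERENCE_NAMES["passage"])

    def test_cross_extractor_jitter_agreement(self):
        """Both extractors track the planted jitter grid (Spearman > 0.9)."""
        prim, ref = [], []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, jp in enumerate(np.linspace(0.3, 4.0, 20)):
                audio, _ = synth_vowel(
                    VoiceSpec(f0_hz=140.0, duration_s=1.2, jitter_pct=float(jp),
                              shimmer_pct=3.0, hnr_db=25.0, seed=100 + i)
                )
                prim.append(extract_features(audio, "phonation")["jitter local"])
                ref.append(
                    extract_reference_features(audio, "phonation")["ref jitter local"]
                )
        assert spearmanr(prim, ref).statistic > 0.9
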