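"""Feature extraction: segmentation, F0, formants, cepstrum, consistency."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import HIGH_SPEC, LOW_SPEC, as_segment, tone
from kittencall.audio import CallSegment, Waveform
from kittencall.features import (DEFAULT_CONFIG, VocalTractSpec, cepstral_peak,
                                 consistency, expected_formant_count,
                                 extract_all, extract_features, formant_params,
                                 peak_frequency, segment_calls, source_params,
                                 time_params, track_f0, F0Track)
from kittencall.synth import CallSpec, PARAMETER_COLUMNS, synthesize_call

FS = 44100


def burst(duration_s: float, amp: float, fs: int = FS,
          freq: float = 1000.0, edge_s: float = 0.005) -> np.ndarray:
    """Flat-top tone burst with short cosine edges (sharp onset/offset, so
    the 5% amplitude criterion finds the true boundaries)."""
    t = np.arange(int(duration_s * fs)) / fs
    ramp = np.minimum(np.minimum(t, duration_s - t) / edge_s, 1.0)
    env = 0.5 - 0.5 * np.cos(np.pi * np.clip(ramp, 0.0, 1.0))
    return amp * env * np.sin(2 * np.pi * freq * t)


def embed(chunks: list[np.ndarray], gaps_s: list[float], noise: float = 0.001,
          fs: int = FS, seed: int = 0) -> Waveform:
    rng = np.random.default_rng(seed)
    parts = [np.zeros(int(0.3 * fs))]
    for i, c in enumerate(chunks):
        parts.append(c)
        parts.append(np.zeros(int((gaps_s[i] if i < len(gaps_s) else 0.3) * fs)))
    x = np.concatenate(parts)
    return Waveform(x + rng.normal(0, noise, x.size), fs)


class TestSegmentation:
    def test_single_burst_boundaries(self):
        w = embed([burst(0.4, 0.8)], [])
        segs = segment_calls(w)
        assert len(segs) == 1
        assert abs(segs[0].duration_ms - 400.0) < 10.0
        assert abs(segs[0].onset / FS - 0.3) < 0.01

    def test_two_bursts_ici(self):
        w = embed([burst(0.3, 0.8), burst(0.3, 0.8)], [1.0])
        segs = segment_calls(w)
        assert len(segs) == 2
        tp = time_params(segs)
        assert abs(tp[0]["ici_ms"] - 1000.0) < 10.0
        assert tp[1]["ici_ms"] is None

    def test_low_contrast_burst_rejected(self):
        """A burst whose envelope rises only ~4% of the background-to-peak
        contrast fails the 5% amplitude criterion, while a clearly louder
        burst in the same noise passes (oracle: direct envelope comparison
        on the constructed signals)."""
        from kittencall.features import smoothed_envelope
        t = np.arange(int(1.5 * FS)) / FS
        floor = 0.2 * np.sin(2 * np.pi * 3000 * t)  # constant-envelope floor
        lo = int(0.5 * FS)

        def with_burst(rel_gain):
            x = floor.copy()
            n = int(0.3 * FS)
            x[lo:lo + n] *= 1.0 + rel_gain
            return Waveform(x, FS)

        weak, strong = with_burst(0.04), with_burst(0.5)
        env = smoothed_envelope(weak)
        bg = float(np.percentile(env, 10))
        # oracle: the peak sits only ~4% above the floor, under the 5%
        # criterion relative to the call maximum
        assert (env.max() - bg) <= 0.05 * env.max()
        assert segment_calls(weak) == []
        assert len(segment_calls(strong)) == 1

    def test_all_silence_gives_empty_list(self):
        w = Waveform(np.zeros(FS) + 1e-6, FS)
        assert segment_calls(w) == []

    def test_symmetric_envelope_peaktime(self):
        """A symmetric envelope peaks at half the segment duration."""
        t = np.arange(int(0.4 * FS)) / FS
        x = 0.8 * np.sin(np.pi * t / 0.4) ** 2 * np.sin(2 * np.pi * 1000 * t)
        w = embed([x], [])
        seg = segment_calls(w)[0]
        tp = time_params([seg])[0]
        half = seg.duration_ms / 2000.0
        assert abs(tp["peaktime_s"] - half) < 0.015


class TestF0Tracking:
    def test_constant_tone_all_voiced(self):
        seg = as_segment(tone(1300.0, 0.5, harmonics=5))
        track = track_f0(seg)
        assert track.voiced.all()
        assert np.all(np.abs(track.f0 - 1300.0) / 1300.0 < 0.01)

    def test_white_noise_mostly_unvoiced(self):
        """Across 20 noise fixtures, at least 80% of frames are unvoiced."""
        rng = np.random.default_rng(2)
        fracs = []
        for _ in range(20):
            seg = as_segment(Waveform(rng.normal(0, 0.3, FS // 2), FS))
            track = track_f0(seg)
            fracs.append(1.0 - track.voiced.mean())
        assert np.mean(fracs) >= 0.8

    def test_noise_gap_is_unvoiced_run(self):
        fs = FS
        t = np.arange(int(0.6 * fs)) / fs
        x = 0.7 * np.sin(2 * np.pi * 1000 * t)
        rng = np.random.default_rng(3)
        a, b = int(0.2 * fs), int(0.4 * fs)
        x[a:b] = rng.normal(0, 0.5, b - a)
        track = track_f0(as_segment(Waveform(x, fs)))
        inside = (track.frame_times > 0.21) & (track.frame_times < 0.39)
        outside = (track.frame_times < 0.18) | (track.frame_times > 0.42)
        assert (~track.voiced[inside]).mean() > 0.8
        assert track.voiced[outside].all()

    def test_too_short_segment_errors(self):
        seg = as_segment(tone(1000.0, 0.005))
        with pytest.raises(ValueError):
            track_f0(seg)

    def test_frame_count_matches_duration(self, low_call):
        track = track_f0(low_call)
        expected = low_call.duration_ms / 10.0
        assert abs(track.n_frames - expected) <= 1


class TestSourceParams:
    def test_hand_computable_statistics(self):
        track = F0Track(frame_times=np.array([0.005, 0.015, 0.025]),
                        f0=np.array([1000.0, 1200.0, 1400.0]),
                        hnr=np.array([20.0, 25.0, 22.0]))
        sp = source_params(track)
        assert sp["mean_f0"] == 1200.0
        assert sp["min_f0"] == 1000.0
        assert sp["max_f0"] == 1400.0
        assert sp["voiced_pct"] == 100.0
        assert sp["max_hnr_db"] == 25.0

    def test_voiced_percentage_arithmetic(self):
        f0 = np.full(100, 900.0)
        f0[:4] = np.nan
        track = F0Track(frame_times=np.arange(100) * 0.01 + 0.005, f0=f0,
                        hnr=np.full(100, 20.0))
        assert source_params(track)["voiced_pct"] == 96.0

    def test_zero_voiced_is_missing_record(self):
        track = F0Track(frame_times=np.array([0.005, 0.015]),
                        f0=np.array([np.nan, np.nan]),
                        hnr=np.array([np.nan, np.nan]))
        sp = source_params(track)
        assert sp["mean_f0"] is None and sp["voiced_pct"] == 0.0


class TestSpectralShape:
    def test_peak_frequency_pure_tone(self):
        seg = as_segment(tone(2000.0, 0.5))
        bin_hz = FS / seg.n_samples
        assert abs(peak_frequency(seg) - 2000.0) <= bin_hz

    def test_peak_frequency_second_harmonic(self):
        t = np.arange(FS // 2) / FS
        x = 0.3 * np.sin(2 * np.pi * 800 * t) + 0.8 * np.sin(2 * np.pi * 1600 * t)
        seg = as_segment(Waveform(x, FS))
        bin_hz = FS / seg.n_samples
        assert abs(peak_frequency(seg) - 1600.0) <= bin_hz

    def test_peak_frequency_dc(self):
        seg = as_segment(Waveform(np.full(1000, 0.5), FS))
        assert peak_frequency(seg) == 0.0

    def test_cepstral_quefrency_tracks_fundamental(self):
        for f0, expected_ms in ((100.0, 10.0), (1000.0, 1.0)):
            spec = CallSpec(duration_ms=200.0, f0_min=f0, f0_mean=f0,
                            f0_max=f0, formants=())
            seg = as_segment(synthesize_call(spec, seed=3))
            q = cepstral_peak(seg)["quefrency_ms"]
            assert abs(q - expected_ms) / expected_ms < 0.02

    def test_cepstral_peak_higher_for_clean_tone(self, low_call):
        rng = np.random.default_rng(4)
        clean = cepstral_peak(low_call)["value"]
        x = low_call.samples
        noisy = x + rng.normal(0, np.sqrt(np.mean(x ** 2)), x.size)  # 0 dB SNR
        noisy_val = cepstral_peak(
            as_segment(Waveform(noisy / np.abs(noisy).max(), FS)))["value"]
        assert clean > noisy_val

    def test_cepstral_too_short_errors(self):
        seg = as_segment(tone(1000.0, 0.005))
        with pytest.raises(ValueError):
            cepstral_peak(seg)

    def test_consistency_stationary_tone(self):
        seg = as_segment(tone(1300.0, 0.4, harmonics=4))
        assert consistency(seg) >= 0.99

    def test_consistency_noise_below_tone(self):
        """Independent white-noise slices correlate less than a stationary
        tone (oracle: direct computation over 20 fixtures)."""
        rng = np.random.default_rng(5)
        tone_val = consistency(as_segment(tone(1300.0, 0.4, harmonics=4)))
        noise_vals = [
            consistency(as_segment(Waveform(rng.normal(0, 0.3, FS // 4), FS)))
            for _ in range(20)
        ]
        assert max(noise_vals) < tone_val

    def test_consistency_too_short_is_missing(self):
        assert consistency(as_segment(tone(1000.0, 0.012))) is None


class TestFormants:
    def test_recovery_on_canonical_calls(self, low_call, high_call):
        for seg, spec in ((low_call, LOW_SPEC), (high_call, HIGH_SPEC)):
            fp, _ = formant_params(seg)
            for i, name in enumerate(("f1", "f2", "f3")):
                truth = spec.formants[i][0]
                assert abs(fp[f"mean_{name}"] - truth) / truth < 0.05, (
                    name, fp[f"mean_{name}"], truth)

    def test_f2_minus_f1_definition(self, low_call):
        fp, _ = formant_params(low_call)
        assert fp["f2_minus_f1"] == fp["mean_f2"] - fp["mean_f1"]

    def test_deterministic(self, low_call):
        a, _ = formant_params(low_call)
        b, _ = formant_params(low_call)
        assert a == b

    def test_low_rate_input_rejected(self):
        seg = as_segment(Waveform(np.random.default_rng(0).normal(0, 0.1, 8000),
                                  16000))
        with pytest.raises(ValueError):
            formant_params(seg)


class TestExpectedFormantCount:
    @pytest.mark.parametrize("length_m,expected", [
        (0.035, 4),   # 9-11 day kitten vocal tract, 20 kHz cut-off
        (0.0175, 2),  # halving the tract halves the count
        (0.03, 3),    # 2*0.03/350*20000 = 3.43 -> 3
    ])
    def test_uniform_tube_count(self, length_m, expected):
        v = VocalTractSpec(length_m=length_m)
        assert expected_formant_count(v) == expected

    def test_invalid_tract(self):
        with pytest.raises(ValueError):
            VocalTractSpec(length_m=-0.03)


class TestExtractAll:
    def test_round_trip_clean_call(self, low_call):
        feats = extract_features(low_call)
        assert abs(feats.call_duration_ms - LOW_SPEC.duration_ms) <= 5.0
        assert abs(feats.mean_f0 - LOW_SPEC.f0_mean) / LOW_SPEC.f0_mean < 0.02
        assert abs(feats.min_f0 - LOW_SPEC.f0_min) / LOW_SPEC.f0_min < 0.02
        assert abs(feats.max_f0 - LOW_SPEC.f0_max) / LOW_SPEC.f0_max < 0.02
        assert feats.voiced_pct == 100.0
        assert feats.f2_minus_f1 == feats.mean_f2 - feats.mean_f1

    def test_monotone_tonality_under_noise(self, low_call):
        """Adding broadband noise at increasing levels never increases
        MaxHNR or the cepstral peak height (5 SNR steps)."""
        rng = np.random.default_rng(6)
        x = low_call.samples
        rms = np.sqrt(np.mean(x ** 2))
        hnrs, ceps = [], []
        for snr_db in (60, 30, 20, 10, 0):
            noisy = x + rng.normal(0, rms * 10 ** (-snr_db / 20), x.size)
            seg = as_segment(Waveform(noisy / np.abs(noisy).max(), FS))
            hnrs.append(source_params(track_f0(seg))["max_hnr_db"])
            ceps.append(cepstral_peak(seg)["value"])
        assert all(a >= b - 1e-9 for a, b in zip(hnrs, hnrs[1:]))
        assert all(a >= b - 1e-9 for a, b in zip(ceps, ceps[1:]))

    def test_empty_input_gives_empty_table_with_header(self):
        table = extract_all([], [])
        assert len(table) == 0
        assert list(table.columns)[-22:] == PARAMETER_COLUMNS

    def test_label_mismatch_errors(self, low_call):
        with pytest.raises(ValueError, match="label"):
            extract_all([low_call], [])

    def test_f0_ordering_on_extracted_cohort(self, audio_cohort):
        t = audio_cohort["table"].dropna(subset=["MinF0 [Hz]"])
        assert (t["MinF0 [Hz]"] <= t["MeanF0 [Hz]"] + 1e-9).all()
        assert (t["MeanF0 [Hz]"] <= t["MaxF0 [Hz]"] + 1e-9).all()
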