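"""Non-linear-phenomena detection and agreement scoring."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from conftest import LOW_SPEC, as_segment
from kittencall.audio import Waveform
from kittencall.features import F0Track, track_f0
from kittencall.nlp import (DEFAULT_NLP_CONFIG, NLPAnnotation, classify_call,
                            detect_chaos, detect_jumps, detect_subharmonics,
                            nlp_condition_stats, percent_agreement)
from kittencall.synth import CallSpec, NLPEvent, synthesize_call

FS = 44100


def jump_spec(ratio: float = 1.45) -> CallSpec:
    return CallSpec(duration_ms=500.0, f0_min=950.0, f0_mean=1250.0,
                    f0_max=1500.0,
                    formants=((2100.0, 1100.0), (7000.0, 2000.0),
                              (11300.0, 2000.0), (16000.0, 3000.0)),
                    nlp_events=(NLPEvent("jump", 180.0, 320.0, ratio),))


class TestJumps:
    def test_injected_step_detected(self):
        seg = as_segment(synthesize_call(jump_spec(), seed=1))
        events = detect_jumps(track_f0(seg))
        assert len(events) >= 1
        assert any(130 < e.start_ms < 380 for e in events)

    def test_smooth_rise_fall_clean(self, low_call):
        assert detect_jumps(track_f0(low_call)) == []

    def test_vibrato_not_a_jump(self):
        """+-3% vibrato stays below the jump threshold at every frame pair
        (oracle: exhaustive scan of the tracked contour)."""
        t = np.arange(int(0.5 * FS)) / FS
        f0 = 1200.0 * (1.0 + 0.03 * np.sin(2 * np.pi * 8.0 * t))
        phase = 2 * np.pi * np.cumsum(f0) / FS
        x = sum(np.sin(k * phase) / k for k in (1, 2, 3))
        track = track_f0(as_segment(Waveform(0.8 * x / np.abs(x).max(), FS)))
        f = track.f0[track.voiced]
        assert np.all(np.abs(np.diff(f)) / f[:-1]
                      < DEFAULT_NLP_CONFIG.jump_rel_threshold)  # oracle
        assert detect_jumps(track) == []


class TestSubharmonics:
    def test_injected_half_f0_detected(self):
        spec = CallSpec(
            duration_ms=500.0, f0_min=950.0, f0_mean=1250.0, f0_max=1500.0,
            formants=((2100.0, 1100.0), (7000.0, 2000.0), (11300.0, 2000.0),
                      (16000.0, 3000.0)),
            nlp_events=(NLPEvent("subharmonic", 100.0, 400.0, -6.0),),
        )
        seg = as_segment(synthesize_call(spec, seed=2))
        track = track_f0(seg)
        events = detect_subharmonics(seg, track)
        assert events
        lo = min(e.start_ms for e in events)
        hi = max(e.end_ms for e in events)
        assert lo < 150 + 25 and hi > 350 - 25  # span recovered +-~2 frames

    def test_clean_call_has_none(self, low_call):
        assert detect_subharmonics(low_call, track_f0(low_call)) == []

    def test_third_subharmonic_detected(self):
        """Components at F0/3 multiples also count as subharmonics."""
        t = np.arange(int(0.5 * FS)) / FS
        f0 = 1200.0
        x = sum(np.sin(2 * np.pi * f0 * k * t) / k for k in (1, 2, 3))
        for m in (1 / 3, 2 / 3, 4 / 3, 5 / 3):
            x += 0.35 * np.sin(2 * np.pi * f0 * m * t)
        seg = as_segment(Waveform(0.8 * x / np.abs(x).max(), FS))
        events = detect_subharmonics(seg, track_f0(seg))
        assert events and all(e.type == "subharmonic" for e in events)


class TestChaos:
    def test_injected_noise_span_overlaps(self):
        spec = CallSpec(
            duration_ms=600.0, f0_min=950.0, f0_mean=1250.0, f0_max=1500.0,
            formants=((2100.0, 1100.0), (7000.0, 2000.0), (11300.0, 2000.0),
                      (16000.0, 3000.0)),
            nlp_events=(NLPEvent("chaos", 250.0, 400.0, 0.0),),
        )
        seg = as_segment(synthesize_call(spec, seed=3))
        events = detect_chaos(seg, track_f0(seg))
        assert events
        inter = sum(max(0.0, min(e.end_ms, 400) - max(e.start_ms, 250))
                    for e in events)
        union = (max(max(e.end_ms for e in events), 400)
                 - min(min(e.start_ms for e in events), 250))
        assert inter / union >= 0.5  # Jaccard overlap with the true span

    def test_clean_call_has_none(self, low_call):
        assert detect_chaos(low_call, track_f0(low_call)) == []

    def test_full_call_noise_single_event(self):
        rng = np.random.default_rng(4)
        n = int(0.5 * FS)
        t = np.arange(n) / FS
        ramp = np.minimum(np.minimum(t, 0.5 - t) / 0.01, 1.0)
        x = rng.normal(0, 0.3, n) * ramp
        seg = as_segment(Waveform(x, FS))
        events = detect_chaos(seg, track_f0(seg))
        assert len(events) == 1
        assert (events[0].end_ms - events[0].start_ms) >= 0.9 * 500.0


class TestClassifyCall:
    def test_jump_plus_chaos_morphology(self):
        spec = CallSpec(
            duration_ms=600.0, f0_min=950.0, f0_mean=1250.0, f0_max=1500.0,
            formants=((2100.0, 1100.0), (7000.0, 2000.0), (11300.0, 2000.0),
                      (16000.0, 3000.0)),
            nlp_events=(NLPEvent("jump", 150.0, 280.0, 1.5),
                        NLPEvent("chaos", 380.0, 520.0, 0.0)),
        )
        ann = classify_call(as_segment(synthesize_call(spec, seed=5)))
        assert ann.jump and ann.chaos and not ann.subharmonic
        assert not ann.harmonic

    def test_subharmonic_morphology(self):
        spec = CallSpec(
            duration_ms=500.0, f0_min=950.0, f0_mean=1250.0, f0_max=1500.0,
            formants=((2100.0, 1100.0), (7000.0, 2000.0), (11300.0, 2000.0),
                      (16000.0, 3000.0)),
            nlp_events=(NLPEvent("subharmonic", 50.0, 450.0, -8.0),),
        )
        ann = classify_call(as_segment(synthesize_call(spec, seed=6)))
        assert ann.subharmonic

    def test_clean_call_is_harmonic(self, low_call):
        ann = classify_call(low_call)
        assert ann.harmonic and not ann.any_nlp

    def test_gain_invariance(self, low_call):
        """Flags do not change when the waveform is scaled by a constant."""
        spec = jump_spec()
        w = synthesize_call(spec, seed=7)
        a = classify_call(as_segment(w))
        b = classify_call(as_segment(Waveform(0.05 * w.samples, FS)))
        assert (a.jump, a.subharmonic, a.chaos) == (b.jump, b.subharmonic, b.chaos)


class TestAgreement:
    @staticmethod
    def _ann(cid, j=False, s=False, c=False):
        return NLPAnnotation(call_id=cid, jump=j, subharmonic=s, chaos=c)

    def test_identical_annotations(self):
        a = [self._ann(f"c{i}", j=i % 2 == 0) for i in range(6)]
        out = percent_agreement(a, list(a))
        assert all(v == 100.0 for v in out.values())

    def test_one_of_four_differs(self):
        a = [self._ann(f"c{i}") for i in range(4)]
        b = [self._ann("c0", j=True)] + [self._ann(f"c{i}") for i in range(1, 4)]
        out = percent_agreement(a, b)
        assert out["jump"] == 75.0
        assert out["total"] == 75.0
        assert out["chaos"] == 100.0

    def test_id_mismatch_errors(self):
        with pytest.raises(ValueError):
            percent_agreement([self._ann("a")], [self._ann("b")])

    def test_detector_agrees_with_ground_truth_on_cohort(self, audio_cohort):
        """>= 90% total agreement between the detectors and the known
        injections, and per-type sensitivity/specificity >= 0.8."""
        rows = audio_cohort["manifest"].rows.set_index("call_id")
        anns = audio_cohort["annotations"]
        truth = [
            NLPAnnotation(call_id=a.call_id,
                          jump=bool(rows.loc[a.call_id, "true_jump"]),
                          subharmonic=bool(rows.loc[a.call_id, "true_subharmonic"]),
                          chaos=bool(rows.loc[a.call_id, "true_chaos"]))
            for a in anns
        ]
        agreement = percent_agreement(anns, truth)
        assert agreement["total"] >= 90.0
        for typ in ("jump", "subharmonic", "chaos"):
            tp = sum(getattr(t, typ) and getattr(d, typ)
                     for t, d in zip(truth, anns))
            fn = sum(getattr(t, typ) and not getattr(d, typ)
                     for t, d in zip(truth, anns))
            fp = sum((not getattr(t, typ)) and getattr(d, typ)
                     for t, d in zip(truth, anns))
            tn = sum((not getattr(t, typ)) and not getattr(d, typ)
                     for t, d in zip(truth, anns))
            assert tp / (tp + fn) >= 0.8, typ
            assert tn / (tn + fp) >= 0.8, typ


class TestConditionStats:
    def test_subharmonics_only_in_high(self, audio_cohort):
        stats = nlp_condition_stats(
            audio_cohort["annotations"],
            audio_cohort["table"][["call_id", "kitten_id", "condition"]])
        pct = stats["per_kitten"]
        low = pct[pct.condition == "Low"]["subharmonic"].mean()
        high = pct[pct.condition == "High"]["subharmonic"].mean()
        assert high > low
        assert high > 5.0

    def test_identical_percentages_give_p_one(self):
        anns = []
        labels = []
        for k in range(3):
            for cond in ("Low", "High"):
                for i in range(4):
                    cid = f"k{k}_{cond}_{i}"
                    anns.append(NLPAnnotation(call_id=cid, jump=i == 0,
                                              subharmonic=False, chaos=False))
                    labels.append({"call_id": cid, "kitten_id": f"k{k}",
                                   "condition": cond})
        stats = nlp_condition_stats(anns, pd.DataFrame(labels))
        assert stats["wilcoxon"]["jump"].p == 1.0

    def test_signed_rank_matches_hand_computation(self):
        """{Low: [20, 20, 30], High: [10, 10, 15]}: all differences
        positive, so the signed-rank statistic (sum of negative ranks,
        Pratt convention) is 0."""
        anns, labels = [], []
        low_pct = {0: 0.2, 1: 0.2, 2: 0.3}
        high_pct = {0: 0.1, 1: 0.1, 2: 0.15}
        for k in range(3):
            for cond, pcts in (("Low", low_pct), ("High", high_pct)):
                n = 20
                n_jump = int(round(pcts[k] * n))
                for i in range(n):
                    cid = f"k{k}_{cond}_{i}"
                    anns.append(NLPAnnotation(call_id=cid, jump=i < n_jump,
                                              subharmonic=False, chaos=False))
                    labels.append({"call_id": cid, "kitten_id": f"k{k:02d}",
                                   "condition": cond})
        stats = nlp_condition_stats(anns, pd.DataFrame(labels))
        assert stats["wilcoxon"]["jump"].statistic == 0.0
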