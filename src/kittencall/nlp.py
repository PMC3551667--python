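"""Detection of non-linear phenomena (NLP) in isolation calls.

An automated, reproducible stand-in for visual spectrogram classification
of the three NLP types of irregular vocal-fold vibration:

* frequency jumps — abrupt upward/downward steps of the fundamental
  frequency between otherwise locally stable stretches;
* subharmonics — additional spectral components at integer fractions of F0
  (F0/2, F0/3), i.e. interleaving components between the harmonics;
* deterministic chaos — broad-band aperiodic stretches that may retain
  traces of harmonic structure (high spectral flatness).

A call containing none of these is classified as harmonic. Detector
thresholds are module constants fixed by calibration on synthetic fixtures
with known injections (sensitivity and specificity >= 0.8 per type) and
recorded in :class:`NLPConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

from .audio import CallSegment
from .features import DEFAULT_CONFIG, F0Track, FeatureConfig, track_f0
from .stats import wilcoxon_signed


@dataclass(frozen=True)
class NLPConfig:
    """Detector thresholds (calibrated on ground-truthed synthetic calls)."""

    jump_rel_threshold: float = 0.18  # |dF0|/F0 between stable anchors
    jump_stability_threshold: float = 0.08  # max |dF0|/F0 around an anchor
    jump_max_gap_frames: int = 4  # anchors may bridge unstable boundary frames
    jump_edge_margin_ms: float = 50.0  # onset/offset region excluded
    subharmonic_ratio_threshold: float = 0.02  # E(F0/2 or F0/3) / E(F0)
    subharmonic_min_frames: int = 3
    subharmonic_min_hnr_db: float = 5.0  # only clearly harmonic frames count
    subharmonic_odd_even_threshold: float = 0.25  # halved-track criterion
    subharmonic_tripled_threshold: float = 0.5  # tripled-track criterion
    chaos_flatness_threshold: float = 0.035  # noise-corrected flatness (0..1)
    chaos_min_frames: int = 3
    chaos_min_rel_envelope: float = 0.3  # skip quiet (edge/breathy) frames
    chaos_edge_margin_ms: float = 45.0  # breathy onsets/offsets are not chaos
    analysis_window_ms: float = 25.0
    flatness_window_ms: float = 25.0
    flatness_band_hz: tuple[float, float] = (300.0, 15000.0)


DEFAULT_NLP_CONFIG = NLPConfig()


@dataclass(frozen=True)
class NLPEventSpan:
    """A detected event: type plus span in ms from call onset."""

    type: str
    start_ms: float
    end_ms: float


@dataclass(frozen=True)
class NLPAnnotation:
    """Per-call NLP flags; ``harmonic`` is the complement of the other three."""

    call_id: str
    jump: bool
    subharmonic: bool
    chaos: bool
    events: tuple[NLPEventSpan, ...] = ()

    @property
    def harmonic(self) -> bool:
        return not (self.jump or self.subharmonic or self.chaos)

    @property
    def any_nlp(self) -> bool:
        return not self.harmonic


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _frame_spectrum(seg: CallSegment, t_center: float, window_ms: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed power spectrum around ``t_center`` (s from onset)."""
    fs = float(seg.sample_rate)
    x = seg.samples
    n = int(round(window_ms * 1e-3 * fs))
    c = int(round(t_center * fs))
    lo = c - n // 2
    frame = np.zeros(n)
    src = x[max(lo, 0) : min(lo + n, x.size)]
    frame[max(-lo, 0) : max(-lo, 0) + src.size] = src
    frame = frame * hann(n, sym=False)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    power = np.abs(np.fft.rfft(frame, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    return freqs, power


def _band_energy(freqs: np.ndarray, power: np.ndarray, f: float,
                 rel_halfwidth: float = 0.05) -> float:
    lo, hi = f * (1 - rel_halfwidth), f * (1 + rel_halfwidth)
    m = (freqs >= lo) & (freqs <= hi)
    return float(power[m].sum()) if m.any() else 0.0


def _runs_to_events(mask: np.ndarray, times: np.ndarray, min_frames: int,
                    ev_type: str, step: float) -> list[NLPEventSpan]:
    events = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return events
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_frames:
            events.append(NLPEventSpan(
                ev_type,
                1000.0 * (times[s] - step / 2),
                1000.0 * (times[e] + step / 2),
            ))
    return events


# ---------------------------------------------------------------------------
# detectors
# ---------------------------------------------------------------------------


def detect_jumps(track: F0Track, rel_threshold: float | None = None,
                 config: NLPConfig = DEFAULT_NLP_CONFIG) -> list[NLPEventSpan]:
    """Frequency jumps: frame pairs with |dF0|/F0 above threshold, both
    sides locally stable.

    Near-octave steps (ratio within 6 % of 2 or 1/2) are excluded: they are
    indistinguishable from tracker octave errors at subharmonic onsets, a
    guard any F0-based jump detector needs.
    """
    thr = rel_threshold if rel_threshold is not None else config.jump_rel_threshold
    f0 = track.f0
    t = track.frame_times
    n = len(f0)
    # an anchor frame is voiced and consistent with both neighbours; the
    # frame whose analysis window straddles the step itself often returns a
    # spurious combination period, so jumps are read between the nearest
    # stable anchors (gap of up to jump_max_gap_frames)
    stab = config.jump_stability_threshold
    left_stable = np.zeros(n, dtype=bool)  # consistent with the previous frame
    right_stable = np.zeros(n, dtype=bool)  # consistent with the next frame
    for i in range(n):
        if np.isnan(f0[i]):
            continue
        if i > 0 and not np.isnan(f0[i - 1]):
            left_stable[i] = abs(f0[i] - f0[i - 1]) / f0[i - 1] <= stab
        if i + 1 < n and not np.isnan(f0[i + 1]):
            right_stable[i] = abs(f0[i + 1] - f0[i]) / f0[i] <= stab
    dur_ms = 1000.0 * n * track.frame_step
    margin = config.jump_edge_margin_ms
    events: list[NLPEventSpan] = []
    last_end = -1.0
    for i in range(1, n - 1):
        if not left_stable[i]:
            continue
        for gap in range(1, config.jump_max_gap_frames + 1):
            j = i + gap
            if j >= n - 1:
                break
            if not right_stable[j]:
                continue
            a, b = f0[i], f0[j]
            ratio = b / a
            if abs(b - a) / a <= thr:
                break  # next stable anchor continues the same glide
            if 1.88 <= max(ratio, 1 / ratio) <= 2.12:
                break  # indistinguishable from a tracker octave error
            t0, t1 = 1000.0 * t[i], 1000.0 * t[j]
            if t0 < margin or t1 > dur_ms - margin:
                break
            if t0 > last_end:  # merge chains of overlapping anchor pairs
                events.append(NLPEventSpan("jump", t0, t1))
                last_end = t1
            break
    return events


def detect_subharmonics(seg: CallSegment, track: F0Track,
                        ratio_threshold: float | None = None,
                        config: NLPConfig = DEFAULT_NLP_CONFIG
                        ) -> list[NLPEventSpan]:
    """Subharmonics: sustained spectral energy at F0/2 or F0/3.

    Per voiced frame, the energy in a +-5 % band around F0/2 (and F0/3) is
    compared with the energy at F0. On strong subharmonics the F0 tracker
    legitimately locks onto the doubled period, so a second criterion
    recognises the halved state: the odd multiples of the tracked F0 (the
    subharmonic series) are then far weaker than the even multiples (the
    true harmonics).
    """
    thr = (ratio_threshold if ratio_threshold is not None
           else config.subharmonic_ratio_threshold)
    hits = np.zeros(track.n_frames, dtype=bool)
    for i, (tc, f0) in enumerate(zip(track.frame_times, track.f0)):
        if np.isnan(f0):
            continue
        if (not np.isnan(track.hnr[i])
                and track.hnr[i] < config.subharmonic_min_hnr_db):
            continue  # aperiodic (e.g. chaotic) frame, not a subharmonic
        freqs, power = _frame_spectrum(seg, tc, config.analysis_window_ms)
        e_f0 = _band_energy(freqs, power, f0)
        if e_f0 <= 0:
            continue
        below = max(
            _band_energy(freqs, power, f0 / 2.0),
            _band_energy(freqs, power, f0 / 3.0),
        )
        odd = sum(_band_energy(freqs, power, k * f0) for k in (1, 3, 5))
        even = sum(_band_energy(freqs, power, k * f0) for k in (2, 4, 6))
        halved = even > 0 and odd / even < config.subharmonic_odd_even_threshold
        non3 = sum(_band_energy(freqs, power, k * f0) for k in (1, 2, 4, 5))
        by3 = sum(_band_energy(freqs, power, k * f0) for k in (3, 6))
        tripled = by3 > 0 and non3 / by3 < config.subharmonic_tripled_threshold
        if below / e_f0 > thr or halved or tripled:
            hits[i] = True
    return _runs_to_events(hits, track.frame_times,
                           config.subharmonic_min_frames, "subharmonic",
                           track.frame_step)


def spectral_flatness_track(seg: CallSegment,
                            config: NLPConfig = DEFAULT_NLP_CONFIG,
                            step_s: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame spectral flatness after noise-floor subtraction.

    The call's stationary noise floor (background plus breathy source
    noise) is estimated as the per-bin 10th percentile of the frame power
    spectra and subtracted before the geometric/arithmetic-mean flatness is
    taken, so only *localized* broad-band energy — the chaotic segments —
    raises the measure. Invariant to overall gain.
    """
    fs = float(seg.sample_rate)
    n_frames = max(1, int(round(seg.n_samples / fs / step_s)))
    times = (np.arange(n_frames) + 0.5) * step_s
    spectra = []
    freqs = None
    for tc in times:
        freqs, power = _frame_spectrum(seg, tc, config.flatness_window_ms)
        spectra.append(power)
    S = np.asarray(spectra)
    floor = np.percentile(S, 10, axis=0)
    S = np.maximum(S - floor, 1e-6 * S)
    lo, hi = config.flatness_band_hz
    band = S[:, (freqs >= lo) & (freqs <= hi)] + 1e-300
    flat = np.exp(np.mean(np.log(band), axis=1)) / np.mean(band, axis=1)
    return times, flat


def _raw_flatness(seg: CallSegment, times: np.ndarray, config: NLPConfig
                  ) -> np.ndarray:
    """Uncorrected per-frame spectral flatness (for fully aperiodic calls)."""
    lo, hi = config.flatness_band_hz
    out = np.zeros(times.size)
    for i, tc in enumerate(times):
        freqs, power = _frame_spectrum(seg, tc, config.flatness_window_ms)
        band = power[(freqs >= lo) & (freqs <= hi)] + 1e-300
        out[i] = float(np.exp(np.mean(np.log(band))) / np.mean(band))
    return out


def detect_chaos(seg: CallSegment, track: F0Track | None = None,
                 entropy_threshold: float | None = None,
                 config: NLPConfig = DEFAULT_NLP_CONFIG) -> list[NLPEventSpan]:
    """Chaos: sustained broad-band frames (spectral flatness above threshold).

    Quiet frames (local RMS below ``chaos_min_rel_envelope`` of the loudest
    frame) and the first/last ``chaos_edge_margin_ms`` are skipped: breathy
    call edges are broad-band but are not what a rater would score as a
    chaotic segment. A call that is essentially unvoiced throughout (no
    tonal reference for the noise-floor correction) is scored as one
    chaotic segment spanning its audible extent.
    """
    thr = (entropy_threshold if entropy_threshold is not None
           else config.chaos_flatness_threshold)
    fs = float(seg.sample_rate)
    x = seg.samples
    times, flat = spectral_flatness_track(seg, config)
    rms = np.array([
        float(np.sqrt(np.mean(x[max(0, int((tc - 0.005) * fs)):
                                int((tc + 0.005) * fs)] ** 2)))
        if int((tc + 0.005) * fs) > max(0, int((tc - 0.005) * fs)) else 0.0
        for tc in times
    ])
    if track is not None and track.n_frames and track.voiced.mean() < 0.2:
        audible = rms >= 0.1 * (rms.max() or 1.0)
        raw = _raw_flatness(seg, times, config)
        if np.median(raw[audible]) > thr:
            return _runs_to_events(audible, times, config.chaos_min_frames,
                                   "chaos", 0.01)
    loud = rms >= config.chaos_min_rel_envelope * (rms.max() or 1.0)
    dur_s = seg.n_samples / fs
    margin = config.chaos_edge_margin_ms / 1000.0
    interior = (times >= margin) & (times <= dur_s - margin)
    return _runs_to_events((flat > thr) & loud & interior, times,
                           config.chaos_min_frames, "chaos", 0.01)


def classify_call(seg: CallSegment, track: F0Track | None = None,
                  call_id: str = "", config: NLPConfig = DEFAULT_NLP_CONFIG,
                  feature_config: FeatureConfig = DEFAULT_CONFIG) -> NLPAnnotation:
    """Run all three detectors; flags are ORs over detected events."""
    if track is None:
        track = track_f0(seg, config=feature_config)
    jumps = detect_jumps(track, config=config)
    subs = detect_subharmonics(seg, track, config=config)
    chaos = detect_chaos(seg, track, config=config)
    return NLPAnnotation(
        call_id=call_id,
        jump=bool(jumps),
        subharmonic=bool(subs),
        chaos=bool(chaos),
        events=tuple(jumps + subs + chaos),
    )


# ---------------------------------------------------------------------------
# agreement and condition statistics
# ---------------------------------------------------------------------------


def percent_agreement(a: list[NLPAnnotation], b: list[NLPAnnotation]
                      ) -> dict[str, float]:
    """Percentage of calls on which two annotation sets agree, per category.

    'total' compares the any-NLP flag (the overall NLP/harmonic decision).
    """
    ids_a = [x.call_id for x in a]
    ids_b = [x.call_id for x in b]
    if sorted(ids_a) != sorted(ids_b):
        raise ValueError("annotation sets cover different call ids")
    lut_b = {x.call_id: x for x in b}
    n = len(a)
    agree = {"total": 0, "jump": 0, "subharmonic": 0, "chaos": 0}
    for x in a:
        y = lut_b[x.call_id]
        agree["total"] += x.any_nlp == y.any_nlp
        agree["jump"] += x.jump == y.jump
        agree["subharmonic"] += x.subharmonic == y.subharmonic
        agree["chaos"] += x.chaos == y.chaos
    return {k: 100.0 * v / n for k, v in agree.items()}


def nlp_condition_stats(annotations: list[NLPAnnotation], labels: pd.DataFrame
                        ) -> dict[str, object]:
    """Per-kitten NLP percentages by condition, with paired Wilcoxon tests.

    ``labels`` must map ``call_id`` to ``kitten_id`` and ``condition``. For
    each kitten and condition the percentage of calls containing each NLP
    type (and any NLP) is computed; conditions are compared across kittens
    with Wilcoxon signed-rank tests. Kittens missing a condition are
    excluded (logged in the result).
    """
    lut = {x.call_id: x for x in annotations}
    df = labels.copy()
    missing = [cid for cid in df["call_id"] if cid not in lut]
    if missing:
        raise ValueError(f"annotations missing for calls: {missing[:5]}...")
    for flag in ("jump", "subharmonic", "chaos", "any_nlp"):
        df[flag] = [getattr(lut[cid], flag) for cid in df["call_id"]]
    pct = (
        df.groupby(["kitten_id", "condition"], sort=True)[
            ["jump", "subharmonic", "chaos", "any_nlp"]
        ].mean() * 100.0
    ).reset_index()

    wide = pct.pivot(index="kitten_id", columns="condition")
    complete = wide.dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    tests = {}
    for flag in ("jump", "subharmonic", "chaos", "any_nlp"):
        if {"Low", "High"} <= set(pct["condition"]) and len(complete) >= 2:
            tests[flag] = wilcoxon_signed(
                complete[(flag, "Low")].to_numpy(),
                complete[(flag, "High")].to_numpy(),
            )
        else:
            tests[flag] = None
    overall = {
        flag: 100.0 * df[flag].mean()
        for flag in ("jump", "subharmonic", "chaos", "any_nlp")
    }
    return {
        "per_kitten": pct,
        "wilcoxon": tests,
        "overall_pct": overall,
        "excluded_kittens": excluded,
    }
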