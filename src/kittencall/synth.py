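"""Parametric kitten-isolation-call synthesizer and cohort generator.

Emulates the study design this package analyses: infant domestic cats
(9-11 days old) recorded in a separation paradigm under two arousal
conditions (Low = separated only, High = separated and handled). Isolation
calls are tonal, with a rise and fall of the fundamental frequency and peak
intensity before the mid-point of the call. The synthesizer renders each
call as a harmonic stack following a rise-fall F0 contour, passed through a
cascade of second-order vocal-tract resonators (source-filter model), with
optional non-linear phenomena (frequency jumps, subharmonics, deterministic
chaos) injected as ground-truthed events.

Default condition profiles reproduce published per-condition means and
standard deviations of the acoustic parameters for this species and age
(durations, inter-call intervals, F0 statistics, formant frequencies and
bandwidths, tonality measures). Individual vocal signatures are modelled as
per-kitten parameter offsets drawn once per kitten and held identical
across conditions.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .audio import DEFAULT_SAMPLE_RATE, Waveform, write_wav

F0_FLOOR_HZ = 75.0
F0_CEIL_HZ = 3000.0

#: the 22 acoustic parameters, in report order (feature-table column names)
PARAMETER_COLUMNS = [
    "Call duration [ms]",
    "ICI [ms]",
    "Peaktime [ms]",
    "MeanF0 [Hz]",
    "MinF0 [Hz]",
    "MaxF0 [Hz]",
    "SDF0 [Hz]",
    "Peak [Hz]",
    "MeanF1 [Hz]",
    "SDF1 [Hz]",
    "BWF1 [Hz]",
    "MeanF2 [Hz]",
    "SDF2 [Hz]",
    "BWF2 [Hz]",
    "MeanF3 [Hz]",
    "SDF3 [Hz]",
    "BWF3 [Hz]",
    "F2-F1 [Hz]",
    "Consistency",
    "Cepstral peak [V]",
    "Voiced [%]",
    "MaxHNR [db]",
]

LABEL_COLUMNS = ["kitten_id", "litter_id", "sex", "body_weight_g", "condition"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndividualProfile:
    """One kitten: identity labels plus its fixed vocal signature.

    ``baseline_shift`` maps parameter names to per-kitten offsets (Hz for
    frequencies, ms for durations, native units otherwise). It is drawn once
    per kitten and applied identically in both arousal conditions, so that
    individual signatures are consistent across conditions.
    """

    kitten_id: str
    litter_id: str
    sex: str  # "male" | "female"
    body_weight_g: float
    baseline_shift: Mapping[str, float]
    first_condition: str = "Low"  # order of exposure, for order-effect checks


@dataclass(frozen=True)
class ConditionEffect:
    """Per-condition target distribution of the acoustic parameters.

    ``target_means``/``target_sds`` hold the per-call population mean and SD
    of every drawn parameter. ``nlp_rates`` are per-call injection
    probabilities for the three non-linear phenomena. ``aperiodicity_db`` is
    the noise-to-harmonic energy ratio of the voice source (dB; more negative
    = more tonal) and ``breathy_edge_ms`` the (min, max) of the uniform draw
    for the noisy onset/offset span; together they realize the per-condition
    tonality contrast (voiced %, MaxHNR, consistency).
    """

    condition: str
    target_means: Mapping[str, float]
    target_sds: Mapping[str, float]
    nlp_rates: Mapping[str, float]
    aperiodicity_db: float
    breathy_edge_ms: tuple[float, float]


@dataclass(frozen=True)
class NLPEvent:
    """A ground-truth non-linear phenomenon: type plus span in ms from call onset."""

    type: str  # "jump" | "subharmonic" | "chaos"
    start_ms: float
    end_ms: float
    param: float = 0.0  # jump: F0 ratio; subharmonic: level dB; chaos: mix dB


@dataclass(frozen=True)
class CallSpec:
    """Complete ground truth for one synthetic call."""

    duration_ms: float
    f0_min: float
    f0_mean: float
    f0_max: float
    formants: tuple[tuple[float, float], ...]  # ((freq Hz, bandwidth Hz), ...) F1..F4
    peak_frac: float = 0.35  # amplitude-peak position, fraction of duration
    f0_peak_frac: float = 0.5  # F0-peak position, fraction of duration
    tilt_db_per_oct: float = -6.0  # source spectral tilt
    aperiodicity_db: float | None = None  # None = clean (no source noise)
    breathy_edge_ms: float = 0.0
    nlp_events: tuple[NLPEvent, ...] = ()
    sample_rate: int = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if not (F0_FLOOR_HZ <= self.f0_min <= self.f0_mean <= self.f0_max <= F0_CEIL_HZ):
            raise ValueError(
                "invalid F0 contour spec: need "
                f"{F0_FLOOR_HZ} <= min <= mean <= max <= {F0_CEIL_HZ}, got "
                f"({self.f0_min}, {self.f0_mean}, {self.f0_max})"
            )
        if not (0.0 < self.peak_frac < 1.0):
            raise ValueError("peak_frac must lie in (0, 1)")
        freqs = [f for f, _ in self.formants]
        if any(b < 0 for _, b in self.formants) or sorted(freqs) != freqs:
            raise ValueError("formants must be ordered with non-negative bandwidths")

    def f0_contour(self, t: np.ndarray) -> np.ndarray:
        """Rise-fall F0 contour (Hz) at times ``t`` (s from call onset).

        Short plateaus at onset, peak and offset make the contour minimum and
        maximum well-defined under frame-based analysis; the exponent of the
        power-law rise/fall is solved so the time-average of the contour
        equals ``f0_mean`` exactly. Jump events multiply the contour by their
        F0 ratio over the event span.
        """
        T = self.duration_ms / 1000.0
        edge = min(0.035, 0.10 * T)  # onset/offset plateau at f0_min
        half_pk = min(0.0125, 0.03 * T)  # peak plateau half-width at f0_max
        t_peak = self.f0_peak_frac * T
        rise = max(t_peak - half_pk - edge, 1e-4)
        fall = max((T - edge) - (t_peak + half_pk), 1e-4)

        span = self.f0_max - self.f0_min
        if span < 1e-9:
            f0 = np.full_like(np.asarray(t, dtype=float), self.f0_min)
        else:
            w_pk = 2 * half_pk / T
            w_rf = (rise + fall) / T
            mu = (self.f0_mean - self.f0_min) / span  # target mean fraction
            q = (mu - w_pk) / max(w_rf, 1e-9)  # required mean of ramp**gamma
            q = float(np.clip(q, 0.05, 0.95))
            gamma = 1.0 / q - 1.0
            tt = np.asarray(t, dtype=float)
            s = np.zeros_like(tt)
            m_rise = (tt >= edge) & (tt < edge + rise)
            s[m_rise] = (tt[m_rise] - edge) / rise
            m_pk = (tt >= edge + rise) & (tt <= edge + rise + 2 * half_pk)
            s[m_pk] = 1.0
            m_fall = (tt > edge + rise + 2 * half_pk) & (tt <= T - edge)
            s[m_fall] = np.clip((T - edge - tt[m_fall]) / fall, 0.0, 1.0)
            f0 = self.f0_min + span * s**gamma

        for ev in self.nlp_events:
            if ev.type == "jump":
                m = (t >= ev.start_ms / 1000.0) & (t < ev.end_ms / 1000.0)
                f0 = np.where(m, f0 * ev.param, f0)
        f0 = np.clip(f0, F0_FLOOR_HZ, F0_CEIL_HZ - 20.0)
        # cap the slope of the power-law tail (a 15 ms moving average):
        # frame-based trackers should see a finite natural glide, with only
        # injected jumps exceeding it. Plateaus (>= 25 ms) are preserved.
        tt = np.asarray(t, dtype=float)
        if tt.size > 100 and np.allclose(np.diff(tt), tt[1] - tt[0]):
            k = max(1, int(round(0.015 / (tt[1] - tt[0]))))
            if k > 1:
                pad = k // 2
                ext = np.concatenate([f0[pad:0:-1], f0, f0[-2 : -pad - 2 : -1]])
                f0 = np.convolve(ext, np.ones(k) / k, mode="same")[pad : pad + tt.size]
        return f0

    def amplitude_envelope(self, t: np.ndarray) -> np.ndarray:
        """Amplitude envelope in [0, 1] with maximum at ``peak_frac`` of duration."""
        T = self.duration_ms / 1000.0
        tp = self.peak_frac * T
        floor = 0.15  # keeps edges above segmentation threshold
        tt = np.clip(np.asarray(t, dtype=float), 0.0, T)
        hump = np.where(
            tt <= tp,
            0.5 - 0.5 * np.cos(np.pi * tt / max(tp, 1e-6)),
            0.5 - 0.5 * np.cos(np.pi * (T - tt) / max(T - tp, 1e-6)),
        )
        env = floor + (1.0 - floor) * hump
        ramp = min(0.003, 0.05 * T)  # 3 ms cosine on/offset so the file starts at 0
        r_on = np.clip(tt / ramp, 0.0, 1.0)
        r_off = np.clip((T - tt) / ramp, 0.0, 1.0)
        return env * (0.5 - 0.5 * np.cos(np.pi * r_on)) * (0.5 - 0.5 * np.cos(np.pi * r_off))

    @property
    def nlp_flags(self) -> dict[str, bool]:
        types = {ev.type for ev in self.nlp_events}
        return {
            "jump": "jump" in types,
            "subharmonic": "subharmonic" in types,
            "chaos": "chaos" in types,
            "harmonic": not types,
        }


# ---------------------------------------------------------------------------
# default condition profiles (study-design reference values)
# ---------------------------------------------------------------------------

_LOW_MEANS = {
    "duration_ms": 566.34,
    "ici_ms": 2072.53,
    "peak_frac": 0.23,
    "f0_min": 931.71,
    "f0_mean": 1305.42,
    "f0_max": 1517.21,
    "sd_f0": 154.99,
    "peak_hz": 1648.68,
    "f1": 2112.80,
    "sd_f1": 696.02,
    "bw1": 1120.22,
    "f2": 7034.30,
    "sd_f2": 981.97,
    "bw2": 1977.26,
    "f3": 11320.63,
    "sd_f3": 1134.20,
    "bw3": 2044.74,
    "consistency": 0.89,
    "cepstral_peak": 2.36,
    "voiced_pct": 98.23,
    "max_hnr_db": 31.73,
}
_LOW_SDS = {
    "duration_ms": 168.62,
    "ici_ms": 1442.76,
    "peak_frac": 0.08,
    "f0_min": 274.86,
    "f0_mean": 238.49,
    "f0_max": 249.64,
    "sd_f0": 37.51,
    "peak_hz": 327.77,
    "f1": 420.47,
    "sd_f1": 273.16,
    "bw1": 466.85,
    "f2": 570.61,
    "sd_f2": 286.65,
    "bw2": 512.96,
    "f3": 552.86,
    "sd_f3": 249.39,
    "bw3": 1128.99,
    "consistency": 0.02,
    "cepstral_peak": 0.59,
    "voiced_pct": 1.71,
    "max_hnr_db": 4.61,
}
_HIGH_MEANS = {
    "duration_ms": 707.10,
    "ici_ms": 1075.38,
    "peak_frac": 0.29,
    "f0_min": 746.65,
    "f0_mean": 1105.10,
    "f0_max": 1316.52,
    "sd_f0": 149.56,
    "peak_hz": 2493.48,
    "f1": 2642.38,
    "sd_f1": 549.43,
    "bw1": 623.80,
    "f2": 6758.39,
    "sd_f2": 987.88,
    "bw2": 1858.01,
    "f3": 11240.16,
    "sd_f3": 1273.83,
    "bw3": 3017.33,
    "consistency": 0.86,
    "cepstral_peak": 2.69,
    "voiced_pct": 96.26,
    "max_hnr_db": 28.78,
}
_HIGH_SDS = {
    "duration_ms": 186.09,
    "ici_ms": 652.32,
    "peak_frac": 0.12,
    "f0_min": 166.58,
    "f0_mean": 184.60,
    "f0_max": 221.48,
    "sd_f0": 37.23,
    "peak_hz": 676.96,
    "f1": 325.62,
    "sd_f1": 159.78,
    "bw1": 376.95,
    "f2": 511.89,
    "sd_f2": 297.99,
    "bw2": 732.96,
    "f3": 524.16,
    "sd_f3": 231.80,
    "bw3": 1602.68,
    "consistency": 0.03,
    "cepstral_peak": 0.61,
    "voiced_pct": 2.67,
    "max_hnr_db": 3.27,
}

#: per-kitten mean percentages of calls with each phenomenon, as rates
LOW_AROUSAL = ConditionEffect(
    condition="Low",
    target_means=_LOW_MEANS,
    target_sds=_LOW_SDS,
    nlp_rates={"jump": 0.20, "subharmonic": 0.0, "chaos": 0.389},
    aperiodicity_db=-30.0,
    breathy_edge_ms=(0.0, 20.0),
)
HIGH_AROUSAL = ConditionEffect(
    condition="High",
    target_means=_HIGH_MEANS,
    target_sds=_HIGH_SDS,
    nlp_rates={"jump": 0.106, "subharmonic": 0.183, "chaos": 0.289},
    aperiodicity_db=-23.0,
    breathy_edge_ms=(10.0, 40.0),
)

DEFAULT_EFFECTS: dict[str, ConditionEffect] = {"Low": LOW_AROUSAL, "High": HIGH_AROUSAL}

#: default F4 resonance (measured formants are F1-F3; a 4th keeps the
#: 20 kHz band realistic for the uniform-tube expectation of 4 formants)
F4_HZ, F4_BW = 16000.0, 3000.0

# signature strength: ratio of between-kitten to within-kitten SD. With the
# total per-call SD fixed at the published value sigma, the between-kitten
# share is sigma*r/sqrt(1+r^2) and the within share sigma/sqrt(1+r^2).
DEFAULT_SIGNATURE_RATIO = 0.5

_BOUNDS = {
    "duration_ms": (250.0, 1600.0),
    "ici_ms": (80.0, 8000.0),
    "peak_frac": (0.08, 0.85),
    "f0_min": (200.0, 2400.0),
    "f0_mean": (250.0, 2500.0),
    "f0_max": (300.0, 2600.0),
    "f1": (1200.0, 4200.0),
    "f2": (5200.0, 8800.0),
    "f3": (9500.0, 13200.0),
    "bw1": (100.0, 2400.0),
    "bw2": (600.0, 3600.0),
    "bw3": (200.0, 7000.0),
    "sd_f0": (20.0, 400.0),
    "sd_f1": (50.0, 2000.0),
    "sd_f2": (50.0, 2200.0),
    "sd_f3": (50.0, 2200.0),
    "peak_hz": (400.0, 6000.0),
    "consistency": (0.3, 1.0),
    "cepstral_peak": (0.1, 8.0),
    "voiced_pct": (40.0, 100.0),
    "max_hnr_db": (5.0, 55.0),
}


def _signature_split(ratio: float) -> tuple[float, float]:
    """(between, within) SD fractions preserving the total per-call SD."""
    denom = np.sqrt(1.0 + ratio * ratio)
    return ratio / denom, 1.0 / denom


# ---------------------------------------------------------------------------
# cohort construction
# ---------------------------------------------------------------------------


def make_cohort(
    n_kittens: int = 18,
    n_litters: int = 6,
    seed: int = 0,
    signature_ratio: float = DEFAULT_SIGNATURE_RATIO,
    weight_range_g: tuple[float, float] = (246.0, 370.0),
) -> list[IndividualProfile]:
    """Create kitten profiles: litters, balanced sexes, weights, signatures.

    Litters are assigned round-robin so every litter is non-empty; sexes
    alternate (exactly balanced for even ``n_kittens``); body weights are
    uniform over ``weight_range_g``. Each kitten's ``baseline_shift`` is a
    per-parameter offset drawn once (SD = between-kitten share of the
    published per-call SD, identical in both conditions). Deterministic for
    a given seed.
    """
    if n_kittens < 1 or n_litters < 1 or n_kittens < n_litters:
        raise ValueError("need n_kittens >= n_litters >= 1")
    b_frac, _ = _signature_split(signature_ratio)
    # between-kitten SDs use the pooled (mean of both conditions) per-call SD
    sig_params = [
        "duration_ms", "ici_ms", "peak_frac", "f0_shift", "sd_f0",
        "f1", "f2", "f3", "bw1", "bw2", "bw3",
        "sd_f1", "sd_f2", "sd_f3", "peak_hz",
        "consistency", "cepstral_peak", "voiced_pct", "max_hnr_db",
    ]
    pooled_sd = {
        k: 0.5 * (_LOW_SDS[k] + _HIGH_SDS[k]) for k in _LOW_SDS
    }
    pooled_sd["f0_shift"] = 0.5 * (_LOW_SDS["f0_mean"] + _HIGH_SDS["f0_mean"])

    profiles: list[IndividualProfile] = []
    for i in range(n_kittens):
        rng = np.random.default_rng(np.random.SeedSequence((seed, 977, i)))
        shift = {
            p: float(rng.normal(0.0, b_frac * pooled_sd[p])) for p in sig_params
        }
        profiles.append(
            IndividualProfile(
                kitten_id=f"K{i + 1:02d}",
                litter_id=f"L{i % n_litters + 1}",
                sex="male" if i % 2 == 0 else "female",
                body_weight_g=float(
                    np.round(rng.uniform(*weight_range_g), 1)
                ),
                baseline_shift=shift,
                first_condition="Low" if (i // 2) % 2 == 0 else "High",
            )
        )
    return profiles


def _call_rng(seed: int, kitten_id: str, condition: str, call_index: int) -> np.random.Generator:
    """Stable per-call generator derived from the root seed."""
    key = zlib.crc32(f"{kitten_id}|{condition}|{call_index}".encode())
    return np.random.default_rng(np.random.SeedSequence((seed, key)))


def _draw(rng: np.random.Generator, name: str, eff: ConditionEffect,
          shift: Mapping[str, float], within_frac: float) -> float:
    """One truncated-Gaussian parameter draw: target mean + signature + noise."""
    mu = eff.target_means[name] + shift.get(name, 0.0)
    sd = within_frac * eff.target_sds[name]
    lo, hi = _BOUNDS[name]
    for _ in range(40):
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mu, lo, hi))


def _draw_f0_triple(rng: np.random.Generator, eff: ConditionEffect,
                    shift: Mapping[str, float], within_frac: float) -> tuple[float, float, float]:
    """Correlated (MinF0, MeanF0, MaxF0) draw with guaranteed ordering.

    The three statistics share one per-kitten register shift (``f0_shift``)
    plus correlated within-call noise; draws violating the ordering are
    rejected and redrawn (rare: the published gaps are ~2.5 SD of the
    difference noise).
    """
    names = ("f0_min", "f0_mean", "f0_max")
    mu = np.array([eff.target_means[n] for n in names]) + shift.get("f0_shift", 0.0)
    sd = within_frac * np.array([eff.target_sds[n] for n in names])
    rho = 0.85
    cov = np.outer(sd, sd) * (rho + (1 - rho) * np.eye(3))
    for _ in range(60):
        v = rng.multivariate_normal(mu, cov, method="cholesky")
        if (
            F0_FLOOR_HZ + 25 < v[0] < v[1] < v[2] < F0_CEIL_HZ - 400
            and v[2] - v[0] > 40.0
        ):
            return float(v[0]), float(v[1]), float(v[2])
    base = np.clip(mu, F0_FLOOR_HZ + 50, F0_CEIL_HZ - 500)
    return float(base[0]), float(max(base[1], base[0] + 20)), float(max(base[2], base[1] + 20))


def _draw_nlp_events(rng: np.random.Generator, eff: ConditionEffect,
                     duration_ms: float) -> tuple[NLPEvent, ...]:
    events: list[NLPEvent] = []
    if rng.random() < eff.nlp_rates.get("jump", 0.0):
        start = rng.uniform(0.25, 0.55) * duration_ms
        length = rng.uniform(0.12, 0.30) * duration_ms
        ratio = rng.uniform(1.35, 1.6)
        if rng.random() < 0.5:
            ratio = 1.0 / ratio
        events.append(NLPEvent("jump", start, min(start + length, 0.9 * duration_ms), ratio))
    if rng.random() < eff.nlp_rates.get("subharmonic", 0.0):
        start = rng.uniform(0.05, 0.25) * duration_ms
        end = start + rng.uniform(0.45, 0.75) * duration_ms
        events.append(NLPEvent("subharmonic", start, min(end, 0.95 * duration_ms),
                               rng.uniform(-13.0, -7.0)))
    if rng.random() < eff.nlp_rates.get("chaos", 0.0):
        start = rng.uniform(0.15, 0.55) * duration_ms
        length = rng.uniform(60.0, 160.0)
        events.append(NLPEvent("chaos", start, min(start + length, 0.9 * duration_ms),
                               rng.uniform(-2.0, 2.0)))
    return tuple(events)


def draw_call_spec(
    rng: np.random.Generator,
    eff: ConditionEffect,
    profile: IndividualProfile,
    signature_ratio: float = DEFAULT_SIGNATURE_RATIO,
) -> CallSpec:
    """Draw one call's ground-truth spec for a kitten under a condition."""
    _, w_frac = _signature_split(signature_ratio)
    shift = profile.baseline_shift
    f0_lo, f0_mid, f0_hi = _draw_f0_triple(rng, eff, shift, w_frac)
    f1 = _draw(rng, "f1", eff, shift, w_frac)
    f2 = _draw(rng, "f2", eff, shift, w_frac)
    f3 = _draw(rng, "f3", eff, shift, w_frac)
    f1, f2, f3 = sorted((f1, f2, f3))
    duration = _draw(rng, "duration_ms", eff, shift, w_frac)
    spec = CallSpec(
        duration_ms=duration,
        f0_min=f0_lo,
        f0_mean=f0_mid,
        f0_max=f0_hi,
        formants=(
            (f1, _draw(rng, "bw1", eff, shift, w_frac)),
            (f2, _draw(rng, "bw2", eff, shift, w_frac)),
            (f3, _draw(rng, "bw3", eff, shift, w_frac)),
            (F4_HZ, F4_BW),
        ),
        peak_frac=_draw(rng, "peak_frac", eff, shift, w_frac),
        f0_peak_frac=float(np.clip(rng.normal(0.5, 0.05), 0.35, 0.65)),
        aperiodicity_db=eff.aperiodicity_db + float(rng.normal(0.0, 1.5)),
        breathy_edge_ms=float(rng.uniform(*eff.breathy_edge_ms)),
        nlp_events=_draw_nlp_events(rng, eff, duration),
    )
    return spec


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------


def _resonator_cascade(x: np.ndarray, formants: Sequence[tuple[float, float]],
                       fs: float) -> np.ndarray:
    """Filter through a cascade of two-pole resonators (unit DC gain each)."""
    y = x
    for f, bw in formants:
        r = np.exp(-np.pi * bw / fs)
        theta = 2.0 * np.pi * f / fs
        a = [1.0, -2.0 * r * np.cos(theta), r * r]
        b = [1.0 + a[1] + a[2]]
        y = lfilter(b, a, y)
    return y


def _harmonic_stack(phase: np.ndarray, f0: np.ndarray, multiples: np.ndarray,
                    tilt_db_per_oct: float, fs: float) -> np.ndarray:
    """Sum of sinusoids at ``multiples`` of F0 with spectral tilt.

    Harmonic phases are coherent (pulse-like source, as produced by a
    glottal excitation), which gives voiced frames the clear comb structure
    a cepstral tonality measure relies on. Components are silenced wherever
    they would exceed 0.46 fs, so sweeping contours do not alias.
    """
    out = np.zeros_like(phase)
    for m in multiples:
        amp = float(m) ** (tilt_db_per_oct / 6.0206)
        mask = (m * f0) < (0.46 * fs)
        if not mask.any():
            continue
        out += amp * mask * np.sin(m * phase)
    return out


def synthesize_call(spec: CallSpec, seed: int = 0) -> Waveform:
    """Render one call to audio.

    Harmonic stack of the F0 contour -> NLP source modifications
    (subharmonic components at odd multiples of F0/2; chaos as
    formant-shaped noise partially replacing the harmonic source) ->
    resonator cascade -> amplitude envelope with peak at ``peak_frac``.
    The result has exactly ``round(duration_ms * fs / 1000)`` samples and
    peak amplitude 1.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5CA11)))
    fs = float(spec.sample_rate)
    n = int(round(spec.duration_ms * fs / 1000.0))
    t = np.arange(n) / fs
    f0 = spec.f0_contour(t)
    phase = 2.0 * np.pi * np.cumsum(f0) / fs

    n_harm = max(3, int(0.46 * fs / float(np.max(f0))) + 2)
    source = _harmonic_stack(phase, f0, np.arange(1, n_harm + 1), spec.tilt_db_per_oct, fs)
    rms_h = float(np.sqrt(np.mean(source**2))) or 1.0

    def _event_mask(ev: NLPEvent, ramp_s: float = 0.005) -> np.ndarray:
        m = np.clip((t - ev.start_ms / 1000.0) / ramp_s, 0.0, 1.0) * np.clip(
            (ev.end_ms / 1000.0 - t) / ramp_s, 0.0, 1.0
        )
        return m

    for ev in spec.nlp_events:
        if ev.type == "subharmonic":
            # odd multiples of F0/2 interleave the harmonic stack
            sub = _harmonic_stack(
                phase, f0, np.arange(0.5, n_harm, 1.0), spec.tilt_db_per_oct, fs
            )
            rms_s = float(np.sqrt(np.mean(sub**2))) or 1.0
            gain = 10.0 ** (ev.param / 20.0) * rms_h / rms_s
            source = source + gain * _event_mask(ev) * sub
        elif ev.type == "chaos":
            mask = _event_mask(ev)
            noise = rng.standard_normal(n)
            rms_n = float(np.sqrt(np.mean(noise**2)))
            gain = 10.0 ** (ev.param / 20.0) * rms_h / rms_n
            # keep a harmonic trace under the noise (broad-band component
            # that may contain traces of harmonic elements)
            source = source * (1.0 - 0.3 * mask) + gain * mask * noise

    if spec.aperiodicity_db is not None:
        noise = rng.standard_normal(n)
        noise *= rms_h / (float(np.sqrt(np.mean(noise**2))) or 1.0)
        source = source + 10.0 ** (spec.aperiodicity_db / 20.0) * noise
        if spec.breathy_edge_ms > 0:
            span = spec.breathy_edge_ms / 1000.0
            edge = np.clip(1.0 - t / span, 0.0, 1.0) + np.clip(
                (t - (t[-1] - span)) / span, 0.0, 1.0
            )
            breath = rng.standard_normal(n)
            breath *= rms_h / (float(np.sqrt(np.mean(breath**2))) or 1.0)
            source = source + 2.0 * edge * breath  # +6 dB over the harmonics

    y = _resonator_cascade(source, spec.formants, fs)
    y = y * spec.amplitude_envelope(t)
    peak = float(np.max(np.abs(y))) or 1.0
    return Waveform(y / peak, spec.sample_rate)


def embed_call(call: Waveform, pad_s: float = 0.15, noise_floor: float = 0.04,
               seed: int = 0) -> Waveform:
    """Place a call in background noise with silence padding on both sides.

    ``noise_floor`` is the background noise sigma relative to the call's
    peak (default 0.04, i.e. roughly -26 dB), so the 5 % amplitude selection
    criterion of the segmenter is exercised but comfortably met.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xBA5E)))
    npad = int(round(pad_s * call.sample_rate))
    x = np.concatenate([np.zeros(npad), call.samples, np.zeros(npad)])
    peak = float(np.max(np.abs(call.samples)))
    x = x + rng.normal(0.0, noise_floor * peak, x.size)
    return Waveform(x / max(1.0, float(np.max(np.abs(x)))), call.sample_rate)


# ---------------------------------------------------------------------------
# cohort synthesis
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """One row per call: labels, file path, drawn ICI, and ground truth."""

    rows: pd.DataFrame  # wav_path + labels + call_index + ici + NLP flags
    specs: dict[str, CallSpec]  # call_id -> ground truth
    out_dir: Path | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(out / "manifest.csv", index=False)
        payload = {
            cid: {
                **{k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(spec).items()},
            }
            for cid, spec in self.specs.items()
        }
        (out / "manifest_specs.json").write_text(
            json.dumps(payload, indent=1, sort_keys=True)
        )

    @classmethod
    def load(cls, out_dir: str | Path) -> "CohortManifest":
        out = Path(out_dir)
        rows = pd.read_csv(out / "manifest.csv")
        payload = json.loads((out / "manifest_specs.json").read_text())
        specs = {}
        for cid, d in payload.items():
            d = dict(d)
            d["formants"] = tuple(tuple(f) for f in d["formants"])
            d["nlp_events"] = tuple(NLPEvent(**ev) for ev in d["nlp_events"])
            specs[cid] = CallSpec(**d)
        return cls(rows=rows, specs=specs, out_dir=out)


def default_low_counts(profiles: Sequence[IndividualProfile],
                       calls_per_cell: int = 10) -> dict[str, int]:
    """Reduced Low-condition call counts of the emulated study design.

    With the default 18-kitten, 10-calls-per-cell cohort, the last two
    kittens contribute only 3 and 5 Low-condition calls (348 calls total).
    """
    counts = {p.kitten_id: calls_per_cell for p in profiles}
    if len(profiles) >= 2 and calls_per_cell == 10:
        counts[profiles[-2].kitten_id] = 3
        counts[profiles[-1].kitten_id] = 5
    return counts


def synthesize_cohort(
    profiles: Sequence[IndividualProfile],
    effects: Mapping[str, ConditionEffect] = DEFAULT_EFFECTS,
    calls_per_cell: int = 10,
    seed: int = 0,
    out_dir: str | Path | None = None,
    low_counts: Mapping[str, int] | None = None,
    signature_ratio: float = DEFAULT_SIGNATURE_RATIO,
    render_audio: bool = True,
) -> CohortManifest:
    """Generate the full two-condition cohort.

    Per call: parameters drawn as condition target mean + kitten signature
    offset + within-kitten noise; NLP events injected at per-condition
    rates; inter-call intervals drawn from the per-condition ICI
    distribution. WAV files (one per call, with background noise padding)
    are written when ``out_dir`` is given and ``render_audio`` is true.
    """
    if not {"Low", "High"} <= set(effects):
        raise ValueError("effects must define both 'Low' and 'High' conditions")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if low_counts is None and calls_per_cell == 10 and len(profiles) == 18:
        low_counts = default_low_counts(profiles, calls_per_cell)

    rows = []
    specs: dict[str, CallSpec] = {}
    for prof in profiles:
        for condition in ("Low", "High"):
            eff = effects[condition]
            n_calls = calls_per_cell
            if condition == "Low" and low_counts is not None:
                n_calls = low_counts.get(prof.kitten_id, calls_per_cell)
            for j in range(n_calls):
                rng = _call_rng(seed, prof.kitten_id, condition, j)
                spec = draw_call_spec(rng, eff, prof, signature_ratio)
                _, w_frac = _signature_split(signature_ratio)
                ici = _draw(rng, "ici_ms", eff, prof.baseline_shift, w_frac)
                call_id = f"{prof.kitten_id}_{condition}_{j:02d}"
                wav_path = f"{call_id}.wav" if out is not None else ""
                if out is not None and render_audio:
                    call = synthesize_call(spec, seed=int(rng.integers(2**31)))
                    write_wav(out / wav_path, embed_call(
                        call, seed=int(rng.integers(2**31))))
                flags = spec.nlp_flags
                rows.append({
                    "call_id": call_id,
                    "wav_path": wav_path,
                    "kitten_id": prof.kitten_id,
                    "litter_id": prof.litter_id,
                    "sex": prof.sex,
                    "body_weight_g": prof.body_weight_g,
                    "condition": condition,
                    "first_condition": prof.first_condition,
                    "call_index": j,
                    "ici_ms": round(ici, 3),
                    "true_jump": flags["jump"],
                    "true_subharmonic": flags["subharmonic"],
                    "true_chaos": flags["chaos"],
                    "true_harmonic": flags["harmonic"],
                })
                specs[call_id] = spec
    manifest = CohortManifest(rows=pd.DataFrame(rows), specs=specs, out_dir=out)
    if out is not None:
        manifest.save(out)
    return manifest


# ---------------------------------------------------------------------------
# distribution-level generator (no audio)
# ---------------------------------------------------------------------------

_COLUMN_TO_PARAM = {
    "Call duration [ms]": "duration_ms",
    "ICI [ms]": "ici_ms",
    "MeanF0 [Hz]": "f0_mean",
    "MinF0 [Hz]": "f0_min",
    "MaxF0 [Hz]": "f0_max",
    "SDF0 [Hz]": "sd_f0",
    "Peak [Hz]": "peak_hz",
    "MeanF1 [Hz]": "f1",
    "SDF1 [Hz]": "sd_f1",
    "BWF1 [Hz]": "bw1",
    "MeanF2 [Hz]": "f2",
    "SDF2 [Hz]": "sd_f2",
    "BWF2 [Hz]": "bw2",
    "MeanF3 [Hz]": "f3",
    "SDF3 [Hz]": "sd_f3",
    "BWF3 [Hz]": "bw3",
    "Consistency": "consistency",
    "Cepstral peak [V]": "cepstral_peak",
    "Voiced [%]": "voiced_pct",
    "MaxHNR [db]": "max_hnr_db",
}


def sample_feature_table(
    profiles: Sequence[IndividualProfile],
    effects: Mapping[str, ConditionEffect] = DEFAULT_EFFECTS,
    calls_per_cell: int = 10,
    seed: int = 0,
    low_counts: Mapping[str, int] | None = None,
    signature_ratio: float = DEFAULT_SIGNATURE_RATIO,
) -> pd.DataFrame:
    """Draw a feature table directly from the statistical call model.

    Produces the same calls-by-(22 parameters + labels) table the audio
    pipeline would, but by sampling parameter values from the per-condition
    target distributions (with per-kitten signature offsets) instead of
    rendering and re-measuring audio. Used for statistical power/null
    simulations where measurement noise of the extraction chain is not the
    object of study.
    """
    if low_counts is None and calls_per_cell == 10 and len(profiles) == 18:
        low_counts = default_low_counts(profiles, calls_per_cell)
    _, w_frac = _signature_split(signature_ratio)
    rows = []
    for prof in profiles:
        for condition in ("Low", "High"):
            eff = effects[condition]
            n_calls = calls_per_cell
            if condition == "Low" and low_counts is not None:
                n_calls = low_counts.get(prof.kitten_id, calls_per_cell)
            for j in range(n_calls):
                rng = _call_rng(seed, prof.kitten_id, condition, j)
                f0_lo, f0_mid, f0_hi = _draw_f0_triple(rng, eff, prof.baseline_shift, w_frac)
                rec = {
                    "call_id": f"{prof.kitten_id}_{condition}_{j:02d}",
                    "kitten_id": prof.kitten_id,
                    "litter_id": prof.litter_id,
                    "sex": prof.sex,
                    "body_weight_g": prof.body_weight_g,
                    "condition": condition,
                    "first_condition": prof.first_condition,
                }
                duration = _draw(rng, "duration_ms", eff, prof.baseline_shift, w_frac)
                peak_frac = _draw(rng, "peak_frac", eff, prof.baseline_shift, w_frac)
                rec["Call duration [ms]"] = duration
                rec["ICI [ms]"] = _draw(rng, "ici_ms", eff, prof.baseline_shift, w_frac)
                rec["Peaktime [ms]"] = peak_frac * duration
                rec["MeanF0 [Hz]"] = f0_mid
                rec["MinF0 [Hz]"] = f0_lo
                rec["MaxF0 [Hz]"] = f0_hi
                for col, p in _COLUMN_TO_PARAM.items():
                    if col in rec or p in ("f0_min", "f0_mean", "f0_max",
                                           "duration_ms", "ici_ms"):
                        continue
                    rec[col] = _draw(rng, p, eff, prof.baseline_shift, w_frac)
                f1, f2, f3 = sorted(
                    (rec["MeanF1 [Hz]"], rec["MeanF2 [Hz]"], rec["MeanF3 [Hz]"])
                )
                rec["MeanF1 [Hz]"], rec["MeanF2 [Hz]"], rec["MeanF3 [Hz]"] = f1, f2, f3
                rec["F2-F1 [Hz]"] = rec["MeanF2 [Hz]"] - rec["MeanF1 [Hz]"]
                rows.append(rec)
    df = pd.DataFrame(rows)
    return df[["call_id"] + LABEL_COLUMNS[:-1] + ["condition", "first_condition"]
              + PARAMETER_COLUMNS].copy()
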