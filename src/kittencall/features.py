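"""Multi-parametric acoustic feature extraction for isolation calls.

Measures, per segmented call, 3 time-related, 4 source-related, 12
filter-related and 3 tonality-related parameters:

* time: call duration, inter-call interval (ICI), peaktime (onset to
  amplitude maximum);
* source: mean/min/max/SD of the fundamental frequency over voiced frames;
* filter: whole-call spectral peak frequency, mean/SD/bandwidth of formants
  F1-F3, F2-F1, and spectral consistency (mean maximum normalised
  cross-covariance of power spectra of successive slices);
* tonality: cepstral peak of the middle 10 ms, percentage of voiced frames,
  and maximum harmonic-to-noise ratio.

F0 is tracked with a normalised-autocorrelation method (75-3000 Hz band,
10 ms steps); formants with per-frame Burg linear prediction (4 formants up
to 20 kHz, 10 ms steps). All thresholds live in :class:`FeatureConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import resample_poly
from scipy.signal.windows import gaussian, hann

from .audio import CallSegment, Waveform
from .synth import LABEL_COLUMNS, PARAMETER_COLUMNS


@dataclass(frozen=True)
class FeatureConfig:
    """All tunable extraction thresholds, with study-design defaults."""

    # segmentation
    min_rel_amplitude: float = 0.05  # amplitude criterion vs background
    envelope_smooth_ms: float = 5.0
    min_call_ms: float = 30.0
    merge_gap_ms: float = 40.0
    # F0 tracking
    fmin_hz: float = 75.0
    fmax_hz: float = 3000.0
    step_s: float = 0.01
    f0_window_factor: float = 3.0  # analysis window = factor / fmin
    voicing_threshold: float = 0.45
    octave_cost: float = 0.05  # per octave, favouring higher candidates
    candidate_floor: float = 0.25
    # formants
    n_formants: int = 4
    max_formant_hz: float = 20000.0
    formant_window_ms: float = 25.0
    lpc_extra_order: int = 0  # order = 2*n_formants + extra
    preemphasis_from_hz: float = 50.0
    max_bandwidth_hz: float = 6000.0
    # second analysis pass for the upper formants: extra spectral tilt
    # compensation (dB/oct equivalent exponent) and the frequency above
    # which its roots are trusted. High-F0 voices with a falling source
    # spectrum bias single-pass LPC: the standard pre-emphasis keeps F1
    # honest while extra flattening is needed before F2-F4 poles settle
    # on the resonances instead of the strongest harmonics below them.
    upper_tilt_exponent: float = 0.6  # ~ +3.6 dB/oct extra
    upper_band_floor_hz: float = 4500.0
    # tonality / spectral shape
    cepstrum_window_ms: float = 10.0
    # context multiple of the cepstrum window: quefrencies up to 1/fmin
    # (13.3 ms) are only resolvable with >= 2 periods in the analysis
    # excerpt, so the centred 10 ms window is padded with surrounding
    # signal to this multiple (clipped to the call bounds)
    cepstrum_context_factor: float = 4.0
    consistency_slice_ms: float = 10.0  # alternative convention: 25 ms


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class F0Track:
    """Frame-wise F0 (Hz; NaN = unvoiced) and harmonicity (dB)."""

    frame_times: np.ndarray  # s, relative to segment onset
    f0: np.ndarray
    hnr: np.ndarray
    frame_step: float = 0.01

    @property
    def voiced(self) -> np.ndarray:
        return ~np.isnan(self.f0)

    @property
    def n_frames(self) -> int:
        return self.f0.size


@dataclass(frozen=True)
class FormantTrack:
    """Frame-wise formant frequencies and bandwidths (NaN = dropped frame)."""

    frame_times: np.ndarray
    formants: np.ndarray  # (n_frames, n_formants) Hz
    bandwidths: np.ndarray  # (n_frames, n_formants) Hz
    frame_step: float = 0.01


@dataclass(frozen=True)
class VocalTractSpec:
    """Uniform-tube vocal tract: length (m), speed of sound (m/s), cut-off (Hz)."""

    length_m: float
    speed_of_sound: float = 350.0
    cutoff_hz: float = 20000.0

    def __post_init__(self) -> None:
        if min(self.length_m, self.speed_of_sound, self.cutoff_hz) <= 0:
            raise ValueError("all vocal-tract quantities must be positive")


@dataclass
class AcousticFeatures:
    """The 22 measured parameters of one call (None = unmeasurable)."""

    call_duration_ms: float | None = None
    ici_ms: float | None = None
    peaktime_s: float | None = None
    mean_f0: float | None = None
    min_f0: float | None = None
    max_f0: float | None = None
    sd_f0: float | None = None
    peak_hz: float | None = None
    mean_f1: float | None = None
    sd_f1: float | None = None
    bw_f1: float | None = None
    mean_f2: float | None = None
    sd_f2: float | None = None
    bw_f2: float | None = None
    mean_f3: float | None = None
    sd_f3: float | None = None
    bw_f3: float | None = None
    f2_minus_f1: float | None = None
    consistency: float | None = None
    cepstral_peak: float | None = None
    voiced_pct: float | None = None
    max_hnr_db: float | None = None

    def as_row(self) -> dict[str, float | None]:
        vals = [
            self.call_duration_ms, self.ici_ms,
            None if self.peaktime_s is None else 1000.0 * self.peaktime_s,
            self.mean_f0, self.min_f0, self.max_f0, self.sd_f0,
            self.peak_hz,
            self.mean_f1, self.sd_f1, self.bw_f1,
            self.mean_f2, self.sd_f2, self.bw_f2,
            self.mean_f3, self.sd_f3, self.bw_f3,
            self.f2_minus_f1, self.consistency, self.cepstral_peak,
            self.voiced_pct, self.max_hnr_db,
        ]
        return dict(zip(PARAMETER_COLUMNS, vals))


# ---------------------------------------------------------------------------
# segmentation and time parameters
# ---------------------------------------------------------------------------


def smoothed_envelope(w: Waveform, smooth_ms: float = 5.0) -> np.ndarray:
    """Rectified amplitude smoothed with a moving average (deterministic
    stand-in for the oscillogram-based manual procedure)."""
    n = max(1, int(round(smooth_ms * 1e-3 * w.sample_rate)))
    kernel = np.ones(n) / n
    return np.convolve(np.abs(w.samples), kernel, mode="same")


def segment_calls(
    w: Waveform,
    min_rel_amplitude: float = 0.05,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> list[CallSegment]:
    """Locate calls as maximal envelope runs above the amplitude criterion.

    The threshold is background level + ``min_rel_amplitude`` x (global peak
    - background), background being the 10th percentile of the smoothed
    envelope. Runs closer than ``merge_gap_ms`` are merged; runs shorter
    than ``min_call_ms`` are rejected. All-silent input gives an empty list.
    """
    env = smoothed_envelope(w, config.envelope_smooth_ms)
    background = float(np.percentile(env, 10))
    peak = float(env.max())
    if peak <= 0 or (peak - background) <= min_rel_amplitude * max(peak, 1e-12):
        return []
    thr = background + min_rel_amplitude * (peak - background)
    above = env > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    # merge runs separated by short gaps
    gap = int(round(config.merge_gap_ms * 1e-3 * w.sample_rate))
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    min_n = int(round(config.min_call_ms * 1e-3 * w.sample_rate))
    return [CallSegment(w, s, e) for s, e in merged if e - s >= min_n]


def time_params(
    segs: list[CallSegment], config: FeatureConfig = DEFAULT_CONFIG
) -> list[dict[str, float | None]]:
    """Call duration (ms), ICI to the next call (ms; None for the last or
    across different source waveforms), and peaktime (s from onset)."""
    out = []
    for i, seg in enumerate(segs):
        env = smoothed_envelope(seg.as_waveform(), config.envelope_smooth_ms)
        ici: float | None = None
        if i + 1 < len(segs) and segs[i + 1].source is seg.source:
            ici = 1000.0 * (segs[i + 1].onset - seg.offset) / seg.sample_rate
        out.append(
            {
                "call_duration_ms": seg.duration_ms,
                "ici_ms": ici,
                "peaktime_s": float(np.argmax(env)) / seg.sample_rate,
            }
        )
    return out


# ---------------------------------------------------------------------------
# F0 tracking (normalised autocorrelation) and source parameters
# ---------------------------------------------------------------------------


def _frame_starts_centers(n: int, fs: float, step_s: float) -> np.ndarray:
    n_frames = max(1, int(round(n / fs / step_s)))
    return (np.arange(n_frames) + 0.5) * step_s


def track_f0(
    seg: CallSegment,
    fmin: float | None = None,
    fmax: float | None = None,
    step: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> F0Track:
    """Frame-wise F0 by normalised autocorrelation with octave-cost
    candidate selection, plus per-frame harmonic-to-noise ratio.

    Each frame's windowed autocorrelation is divided by the window's own
    autocorrelation; candidate lags are local maxima in the pitch band, and
    the winner maximises strength + octave_cost*log2(f/fmin), which guards
    against octave drops onto subharmonics. A frame is voiced when the
    winning strength exceeds the voicing threshold; HNR = 10*log10(r/(1-r)).
    """
    fmin = fmin if fmin is not None else config.fmin_hz
    fmax = fmax if fmax is not None else config.fmax_hz
    step = step if step is not None else config.step_s
    fs = float(seg.sample_rate)
    x = seg.samples
    win_n = int(round(config.f0_window_factor / fmin * fs))
    if x.size < max(win_n // 2, int(2 * fs / fmax)):
        raise ValueError("segment shorter than one analysis window")

    window = hann(win_n, sym=False)
    nfft = 1 << int(np.ceil(np.log2(2 * win_n)))
    w_acf = np.fft.irfft(np.abs(np.fft.rfft(window, nfft)) ** 2)[:win_n]
    w_acf = w_acf / w_acf[0]
    lag_min = max(2, int(np.floor(fs / fmax)))
    lag_max = min(int(np.ceil(fs / fmin)), int(0.9 * win_n))

    centers = _frame_starts_centers(x.size, fs, step)
    f0 = np.full(centers.size, np.nan)
    hnr = np.full(centers.size, np.nan)
    for i, tc in enumerate(centers):
        c = int(round(tc * fs))
        lo, hi = c - win_n // 2, c + win_n - win_n // 2
        frame = np.zeros(win_n)
        src = x[max(lo, 0) : min(hi, x.size)]
        frame[max(-lo, 0) : max(-lo, 0) + src.size] = src
        frame = (frame - frame.mean()) * window
        power = float(frame @ frame)
        if power <= 0:
            continue
        acf = np.fft.irfft(np.abs(np.fft.rfft(frame, nfft)) ** 2)[:win_n]
        r = acf / power
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(w_acf > 0.05, r / w_acf, 0.0)
        band = r[lag_min : lag_max + 1]
        if band.size < 3:
            continue
        interior = np.flatnonzero(
            (band[1:-1] >= band[:-2]) & (band[1:-1] >= band[2:])
            & (band[1:-1] > config.candidate_floor)
        ) + 1
        if interior.size == 0:
            continue
        lags = interior + lag_min
        strengths = band[interior]
        freqs = fs / lags
        scores = strengths + config.octave_cost * np.log2(freqs / fmin)
        best = int(np.argmax(scores))
        strength = float(min(strengths[best], 1.0 - 1e-9))
        if strength < config.voicing_threshold:
            continue
        lag = lags[best]
        if 1 <= lag < win_n - 1:  # parabolic interpolation
            y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
            lag = lag + float(np.clip(delta, -0.5, 0.5))
        f0[i] = fs / lag
        hnr[i] = float(np.clip(10.0 * np.log10(strength / (1.0 - strength)), -10.0, 60.0))
    f0 = _fix_harmonic_locking(f0, hnr)
    return F0Track(frame_times=centers, f0=f0, hnr=hnr, frame_step=step)


def _fix_harmonic_locking(f0: np.ndarray, hnr: np.ndarray,
                          window: int = 21) -> np.ndarray:
    """Snap harmonic-locked frames back onto the local contour.

    Frames where a single strong harmonic dominates (e.g. a harmonic
    sweeping through a narrow formant) lock the autocorrelation onto a
    multiple of the fundamental; such frames have visibly lower
    harmonicity than cleanly tracked ones. Using the locally-windowed
    median of the *trusted* frames (harmonicity at or above the call
    median) as reference, any frame near an integer multiple or
    submultiple of it is divided/multiplied back. A consistent
    period-doubled stretch (true subharmonics spanning the call) matches
    its own median and is left alone. The frame-wise analogue of
    path-based pitch tracking.
    """
    f0 = f0.copy()
    voiced = ~np.isnan(f0)
    if voiced.sum() < 5:
        return f0
    thr = float(np.nanmedian(hnr[voiced]))
    trusted = voiced & (np.nan_to_num(hnr, nan=-99.0) >= thr)
    if trusted.sum() < 3:
        return f0
    half = window // 2
    idx_t = np.flatnonzero(trusted)
    # a locked frame sits at an (almost exact) integer multiple of the
    # nearby true contour; anything less exact is a genuine F0 excursion
    tol = 0.08
    for i in np.flatnonzero(voiced):
        near = idx_t[(idx_t >= i - half) & (idx_t <= i + half) & (idx_t != i)]
        if near.size < 2:
            continue
        med = float(np.median(f0[near]))
        ratio = f0[i] / med
        if ratio > 2.0 - tol:
            k = int(round(ratio))
            if k >= 2 and abs(ratio / k - 1.0) < tol:
                f0[i] /= k
            elif ratio > 1.9:
                # far above any natural excursion: locked on a resonance
                # rather than a harmonic; fall back to the local contour
                f0[i] = med
        elif ratio < 0.5 + tol / 2:
            k = int(round(1.0 / ratio))
            if k >= 2 and abs(ratio * k - 1.0) < tol:
                f0[i] *= k
    return f0


def source_params(track: F0Track, min_hnr_db: float = 5.0
                  ) -> dict[str, float | None]:
    """F0 statistics over voiced frames, voiced %, and maximum HNR.

    The mean/min/max/SD statistics use only voiced frames whose
    harmonicity reaches ``min_hnr_db``: borderline-voiced frames (noisy
    call edges, chaotic stretches) return spurious pitch candidates, and
    excluding them is the automated analogue of the manual pitch-track
    correction the protocol this mirrors relied on. For the same reason
    the extremes are robust (2.5th/97.5th percentile of the retained
    frames): a single residual mistracked frame must not define Min/MaxF0.
    ``voiced_pct`` still counts every voiced frame. Zero voiced frames
    gives a record of Nones (flagged missing values), not an exception.
    """
    voiced = track.voiced
    n = track.n_frames
    if n == 0 or not voiced.any():
        return {
            "mean_f0": None, "min_f0": None, "max_f0": None, "sd_f0": None,
            "voiced_pct": 0.0 if n else None, "max_hnr_db": None,
        }
    good = voiced & (np.nan_to_num(track.hnr, nan=-99.0) >= min_hnr_db)
    f = track.f0[good] if good.any() else track.f0[voiced]
    return {
        "mean_f0": float(f.mean()),
        "min_f0": float(np.percentile(f, 2.5, method="lower")),
        "max_f0": float(np.percentile(f, 97.5, method="higher")),
        "sd_f0": float(f.std(ddof=1)) if f.size > 1 else 0.0,
        "voiced_pct": 100.0 * voiced.sum() / n,
        "max_hnr_db": float(np.nanmax(track.hnr)),
    }


# ---------------------------------------------------------------------------
# spectral shape: peak frequency, cepstral peak, consistency
# ---------------------------------------------------------------------------


def peak_frequency(seg: CallSegment) -> float:
    """Frequency (Hz) of the maximum of the whole-call power spectrum."""
    x = seg.samples
    spec = np.abs(np.fft.rfft(x)) ** 2
    return float(np.argmax(spec) * seg.sample_rate / x.size)


def cepstral_peak(
    seg: CallSegment,
    window_ms: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Real-cepstrum peak of the centred analysis window.

    The cepstrum of the middle ``window_ms`` of the call is searched within
    the quefrency band of the pitch range; a harmonic signal with
    fundamental period T shows its cepstral peak at quefrency T (e.g.
    100 Hz -> 10 ms). Returns the peak height (linear amplitude units,
    higher for clear harmonic structure) and its quefrency in ms.
    """
    window_ms = window_ms if window_ms is not None else config.cepstrum_window_ms
    fs = float(seg.sample_rate)
    x = seg.samples
    win_n = int(round(window_ms * 1e-3 * fs))
    if x.size < win_n:
        raise ValueError(f"call shorter than the {window_ms} ms cepstrum window")
    mid = x.size // 2
    ctx_n = min(int(round(config.cepstrum_context_factor * win_n)), x.size)
    frame = x[mid - ctx_n // 2 : mid - ctx_n // 2 + ctx_n].astype(float)
    frame = frame * hann(frame.size, sym=False)
    nfft = 1 << int(np.ceil(np.log2(8 * win_n)))
    mag = np.abs(np.fft.rfft(frame, nfft))
    floor = 1e-5 * float(mag.max() or 1.0)
    logmag = np.log(mag + floor)
    # remove the smooth spectral-envelope trend so the low-quefrency mass
    # of the source tilt cannot mask the periodicity peak
    bins = np.arange(logmag.size, dtype=float)
    slope, intercept = np.polyfit(bins, logmag, 1)
    cep = np.fft.irfft(logmag - (intercept + slope * bins))
    q_lo = max(2, int(np.floor(fs / config.fmax_hz)))
    q_hi = min(int(np.ceil(fs / config.fmin_hz)), cep.size // 2 - 1)
    band = cep[q_lo : q_hi + 1]
    k = int(np.argmax(band)) + q_lo
    return {"value": float(cep[k]), "quefrency_ms": 1000.0 * k / fs}


def consistency(
    seg: CallSegment,
    slice_ms: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float | None:
    """Mean maximum normalised cross-covariance of power spectra of
    successive call slices (spectral stability; 1 for a stationary tone).

    Returns None (missing value) when the call is shorter than two slices.
    """
    slice_ms = slice_ms if slice_ms is not None else config.consistency_slice_ms
    fs = float(seg.sample_rate)
    n_slice = int(round(slice_ms * 1e-3 * fs))
    x = seg.samples
    n_slices = x.size // n_slice
    if n_slices < 2:
        return None
    nfft = 1 << int(np.ceil(np.log2(2 * n_slice)))
    window = hann(n_slice, sym=False)
    spectra = []
    for i in range(n_slices):
        fr = x[i * n_slice : (i + 1) * n_slice] * window
        spectra.append(np.abs(np.fft.rfft(fr, nfft)) ** 2)
    vals = []
    for u, v in zip(spectra[:-1], spectra[1:]):
        u0 = u - u.mean()
        v0 = v - v.mean()
        denom = math.sqrt(float(u0 @ u0) * float(v0 @ v0))
        if denom <= 0:
            continue
        cc = np.correlate(u0, v0, mode="full")
        vals.append(float(cc.max()) / denom)
    return float(np.mean(vals)) if vals else None


# ---------------------------------------------------------------------------
# formants (Burg linear prediction)
# ---------------------------------------------------------------------------


def _burg(x: np.ndarray, order: int) -> np.ndarray:
    """Burg-method AR coefficients [1, a1..ap] minimising forward+backward
    prediction error."""
    a = np.array([1.0])
    ef = np.asarray(x[1:], dtype=float).copy()
    eb = np.asarray(x[:-1], dtype=float).copy()
    for _ in range(order):
        den = float(ef @ ef + eb @ eb)
        if den <= 0.0 or ef.size < 2:
            break
        k = -2.0 * float(ef @ eb) / den
        a_ext = np.concatenate([a, [0.0]])
        a = a_ext + k * a_ext[::-1]
        ef, eb = ef[1:] + k * eb[1:], eb[:-1] + k * ef[:-1]
    return a


def _frame_resonances(frame: np.ndarray, fs: float, config: FeatureConfig
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Sorted resonance frequencies/bandwidths from the Burg-LPC roots of
    one windowed frame."""
    order = 2 * config.n_formants + config.lpc_extra_order
    a = _burg(frame, order)
    if a.size < 3:
        return np.empty(0), np.empty(0)
    roots = np.roots(a)
    roots = roots[np.imag(roots) > 1e-6]
    freqs = np.angle(roots) * fs / (2.0 * np.pi)
    bws = -np.log(np.clip(np.abs(roots), 1e-12, 1.0)) * fs / np.pi
    keep = (freqs > 150.0) & (freqs < fs / 2 - 100.0) & (bws < config.max_bandwidth_hz)
    freqs, bws = freqs[keep], bws[keep]
    order_idx = np.argsort(freqs)
    return freqs[order_idx], bws[order_idx]


def formant_tracks(
    seg: CallSegment,
    n_formants: int | None = None,
    max_formant: float | None = None,
    step: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> FormantTrack:
    """Per-frame formant frequencies/bandwidths by Burg linear prediction.

    The call is resampled to 2 x max_formant and analysed twice: a standard
    pre-emphasised pass whose lowest stable LPC root gives F1, and a second
    pass with extra spectral-tilt compensation whose roots above
    ``upper_band_floor_hz`` give F2..Fn. Per frame, stable complex roots
    are converted to resonance frequencies and bandwidths. Frames without a
    stable F1 or with fewer than 2 upper resonances are dropped (NaN).
    """
    if n_formants is not None or max_formant is not None or step is not None:
        config = replace(
            config,
            n_formants=n_formants or config.n_formants,
            max_formant_hz=max_formant or config.max_formant_hz,
            step_s=step or config.step_s,
        )
    fs0 = float(seg.sample_rate)
    target_fs = 2.0 * config.max_formant_hz
    if fs0 < target_fs:
        raise ValueError("sample rate below twice the formant ceiling")
    x = seg.samples
    if fs0 != target_fs:
        g = math.gcd(int(target_fs), int(fs0))
        x = resample_poly(x, int(target_fs) // g, int(fs0) // g)
    fs = target_fs
    alpha = math.exp(-2.0 * math.pi * config.preemphasis_from_hz / fs)
    x = np.concatenate([[x[0] * (1 - alpha)], x[1:] - alpha * x[:-1]])
    if config.upper_tilt_exponent > 0:  # flattened copy for the upper band
        spec = np.fft.rfft(x)
        fgrid = np.fft.rfftfreq(x.size, 1.0 / fs)
        x_hi = np.fft.irfft(
            spec * np.maximum(fgrid, 100.0) ** config.upper_tilt_exponent, x.size
        )
    else:
        x_hi = x

    win_n = int(round(config.formant_window_ms * 1e-3 * fs))
    window = gaussian(win_n, std=win_n / 6.0)
    centers = _frame_starts_centers(x.size, fs, config.step_s)
    nf = config.n_formants
    formants = np.full((centers.size, nf), np.nan)
    bandwidths = np.full((centers.size, nf), np.nan)

    def _frame(sig: np.ndarray, c: int) -> np.ndarray:
        lo = c - win_n // 2
        fr = np.zeros(win_n)
        src = sig[max(lo, 0) : min(lo + win_n, sig.size)]
        fr[max(-lo, 0) : max(-lo, 0) + src.size] = src
        return fr * window

    for i, tc in enumerate(centers):
        c = int(round(tc * fs))
        f_lo = _frame(x, c)
        if float(f_lo @ f_lo) <= 0:
            continue
        fr1, bw1 = _frame_resonances(f_lo, fs, config)
        low = fr1 < config.upper_band_floor_hz
        if not low.any():
            continue
        fr2, bw2 = _frame_resonances(_frame(x_hi, c), fs, config)
        hi = fr2 >= max(config.upper_band_floor_hz, 1.3 * fr1[low][0])
        if hi.sum() < 2:
            continue
        fr = np.concatenate([[fr1[low][0]], fr2[hi]])
        bw = np.concatenate([[bw1[low][0]], bw2[hi]])
        m = min(nf, fr.size)
        formants[i, :m] = fr[:m]
        bandwidths[i, :m] = bw[:m]
    return FormantTrack(frame_times=centers, formants=formants,
                        bandwidths=bandwidths, frame_step=config.step_s)


def formant_params(
    seg: CallSegment,
    n_formants: int | None = None,
    max_formant: float | None = None,
    step: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, float | None], FormantTrack]:
    """Per-call mean, SD and bandwidth of F1-F3 plus F2-F1.

    Frames whose local RMS falls below 30% of the loudest frame are
    excluded from the per-call aggregates: in recordings with a noise
    floor their linear-prediction poles reflect the background, not the
    vocal tract.
    """
    track = formant_tracks(seg, n_formants, max_formant, step, config)
    fs = float(seg.sample_rate)
    x = seg.samples
    rms = np.array([
        float(np.sqrt(np.mean(x[max(0, int((tc - 0.005) * fs)):
                                max(0, int((tc - 0.005) * fs)) + 1
                                + int(0.01 * fs)] ** 2)))
        for tc in track.frame_times
    ])
    quiet = rms < 0.3 * (rms.max() or 1.0)
    track = FormantTrack(
        frame_times=track.frame_times,
        formants=np.where(quiet[:, None], np.nan, track.formants),
        bandwidths=np.where(quiet[:, None], np.nan, track.bandwidths),
        frame_step=track.frame_step,
    )
    out: dict[str, float | None] = {}
    valid = ~np.isnan(track.formants[:, 0])
    for j, name in enumerate(("f1", "f2", "f3")):
        col = track.formants[:, j]
        bwcol = track.bandwidths[:, j]
        ok = ~np.isnan(col)
        if ok.sum() == 0:
            out[f"mean_{name}"] = out[f"sd_{name}"] = out[f"bw_{name}"] = None
            continue
        out[f"mean_{name}"] = float(np.nanmean(col))
        out[f"sd_{name}"] = float(np.nanstd(col, ddof=1)) if ok.sum() > 1 else 0.0
        out[f"bw_{name}"] = float(np.nanmean(bwcol))
    if out.get("mean_f1") is not None and out.get("mean_f2") is not None:
        out["f2_minus_f1"] = out["mean_f2"] - out["mean_f1"]
    else:
        out["f2_minus_f1"] = None
    out["n_frames_dropped"] = int((~valid).sum())
    return out, track


def expected_formant_count(v: VocalTractSpec) -> int:
    """Expected number of formants below the cut-off for a uniform tube:
    N = round(2 * L / c * fc)."""
    return int(round(2.0 * v.length_m / v.speed_of_sound * v.cutoff_hz))


# ---------------------------------------------------------------------------
# whole-call extraction
# ---------------------------------------------------------------------------


def extract_features(
    seg: CallSegment,
    ici_ms: float | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> AcousticFeatures:
    """Measure all 22 parameters for one segmented call."""
    feats = AcousticFeatures()
    tp = time_params([seg], config)[0]
    feats.call_duration_ms = tp["call_duration_ms"]
    feats.peaktime_s = tp["peaktime_s"]
    feats.ici_ms = ici_ms

    try:
        track = track_f0(seg, config=config)
        sp = source_params(track)
    except ValueError:
        sp = {k: None for k in ("mean_f0", "min_f0", "max_f0", "sd_f0",
                                "voiced_pct", "max_hnr_db")}
    feats.mean_f0 = sp["mean_f0"]
    feats.min_f0 = sp["min_f0"]
    feats.max_f0 = sp["max_f0"]
    feats.sd_f0 = sp["sd_f0"]
    feats.voiced_pct = sp["voiced_pct"]
    feats.max_hnr_db = sp["max_hnr_db"]

    feats.peak_hz = peak_frequency(seg)
    fp, _ = formant_params(seg, config=config)
    for name in ("f1", "f2", "f3"):
        setattr(feats, f"mean_{name}", fp[f"mean_{name}"])
        setattr(feats, f"sd_{name}", fp[f"sd_{name}"])
        setattr(feats, f"bw_{name}", fp[f"bw_{name}"])
    feats.f2_minus_f1 = fp["f2_minus_f1"]
    feats.consistency = consistency(seg, config=config)
    try:
        feats.cepstral_peak = cepstral_peak(seg, config=config)["value"]
    except ValueError:
        feats.cepstral_peak = None
    return feats


def extract_all(
    segs: list[CallSegment],
    labels: pd.DataFrame | list[dict],
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Build the calls x (22 parameters + labels) feature table.

    ``labels`` must supply one record per segment with the kitten / litter /
    sex / body-weight / condition labels (an ``ici_ms`` field, e.g. from a
    cohort manifest, overrides the segment-measured ICI, which only exists
    when successive calls share a waveform). Missing parameter values are
    NaN, never imputed; a QC summary (dropped-frame counts, missing-value
    counts) is attached as ``df.attrs['qc']``.
    """
    labels_df = pd.DataFrame(labels) if not isinstance(labels, pd.DataFrame) else labels.copy()
    if len(segs) == 0 and len(labels_df) == 0:
        empty = pd.DataFrame(columns=LABEL_COLUMNS + PARAMETER_COLUMNS)
        empty.attrs["qc"] = {"n_calls": 0, "missing_values": {}}
        return empty
    if len(labels_df) != len(segs):
        raise ValueError(
            f"label mismatch: {len(segs)} segments vs {len(labels_df)} label rows"
        )
    missing_labels = [c for c in LABEL_COLUMNS if c not in labels_df.columns]
    if missing_labels:
        raise ValueError(f"labels missing required columns: {missing_labels}")

    tp = time_params(segs, config)
    rows = []
    for i, seg in enumerate(segs):
        ici = labels_df["ici_ms"].iloc[i] if "ici_ms" in labels_df.columns else tp[i]["ici_ms"]
        ici = None if ici is None or (isinstance(ici, float) and np.isnan(ici)) else float(ici)
        feats = extract_features(seg, ici_ms=ici, config=config)
        rows.append(feats.as_row())
    param_df = pd.DataFrame(rows, columns=PARAMETER_COLUMNS, dtype=float)
    out = pd.concat([labels_df.reset_index(drop=True), param_df], axis=1)
    out.attrs["qc"] = {
        "n_calls": len(out),
        "missing_values": {
            c: int(param_df[c].isna().sum())
            for c in PARAMETER_COLUMNS
            if param_df[c].isna().any()
        },
    }
    return out
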