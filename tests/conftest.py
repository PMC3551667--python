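"""Shared fixtures: canonical clean call specs and the default synthetic cohort.

The session-scoped audio cohort renders the full 18-kitten, 348-call study
design once (WAVs in a temp dir), extracts the 22-parameter feature table
and runs the NLP detectors; acceptance-level tests share it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from kittencall.audio import CallSegment, Waveform
from kittencall.pipeline import analyze_cohort_audio
from kittencall.synth import (CallSpec, DEFAULT_EFFECTS, make_cohort,
                              sample_feature_table, synthesize_call,
                              synthesize_cohort)

#: clean canonical call at the Low-arousal condition means
LOW_SPEC = CallSpec(
    duration_ms=566.34, f0_min=931.71, f0_mean=1305.42, f0_max=1517.21,
    formants=((2112.80, 1120.22), (7034.30, 1977.26), (11320.63, 2044.74),
              (16000.0, 3000.0)),
    peak_frac=0.23,
)

#: clean canonical call at the High-arousal condition means
HIGH_SPEC = CallSpec(
    duration_ms=707.10, f0_min=746.65, f0_mean=1105.10, f0_max=1316.52,
    formants=((2642.38, 623.80), (6758.39, 1858.01), (11240.16, 3017.33),
              (16000.0, 3000.0)),
    peak_frac=0.29,
)


def as_segment(w: Waveform) -> CallSegment:
    return CallSegment(w, 0, w.samples.size)


def tone(freq: float, duration_s: float = 0.5, fs: int = 44100,
         harmonics: int = 1, amp: float = 0.8) -> Waveform:
    """Plain (stack of) sinusoid(s), constant amplitude."""
    t = np.arange(int(duration_s * fs)) / fs
    x = sum(np.sin(2 * np.pi * freq * (k + 1) * t) / (k + 1)
            for k in range(harmonics))
    return Waveform(amp * x / np.max(np.abs(x)), fs)


@pytest.fixture(scope="session")
def low_call() -> CallSegment:
    return as_segment(synthesize_call(LOW_SPEC, seed=1))


@pytest.fixture(scope="session")
def high_call() -> CallSegment:
    return as_segment(synthesize_call(HIGH_SPEC, seed=1))


@pytest.fixture(scope="session")
def default_profiles():
    return make_cohort(18, 6, seed=11)


@pytest.fixture(scope="session")
def table_cohort(default_profiles) -> pd.DataFrame:
    """Distribution-level default cohort (no audio)."""
    return sample_feature_table(default_profiles, seed=11)


@pytest.fixture(scope="session")
def audio_cohort(default_profiles, tmp_path_factory):
    """Full default audio cohort: manifest, feature table, NLP annotations."""
    out = tmp_path_factory.mktemp("cohort_audio")
    manifest = synthesize_cohort(default_profiles, DEFAULT_EFFECTS,
                                 calls_per_cell=10, seed=11, out_dir=out)
    table, annotations = analyze_cohort_audio(manifest)
    return {"manifest": manifest, "table": table, "annotations": annotations}
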