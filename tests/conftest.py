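"""Shared fixtures: small spectrograms, synthetic calls, feature draws."""

import numpy as np
import pandas as pd
import pytest

from sealvoc.measurements import Selection
from sealvoc.spectro import Spectrogram, SpectrogramConfig, compute_spectrogram

SR = 96000


@pytest.fixture(scope="session")
def cfg96() -> SpectrogramConfig:
    return SpectrogramConfig(sample_rate=SR)


@pytest.fixture(scope="session")
def cfg48() -> SpectrogramConfig:
    return SpectrogramConfig(sample_rate=48000)


def toy_spectrogram(energy, dfreq=10.0, dt=0.01) -> Spectrogram:
    """Spectrogram wrapper around an arbitrary small energy matrix."""
    return Spectrogram(np.asarray(energy, dtype=float), dfreq, dt)


def full_box(spec: Spectrogram) -> Selection:
    """Selection covering the whole spectrogram extent."""
    return Selection(
        start_time=-1e-9,
        end_time=spec.times[-1] + spec.time_step,
        low_freq=-1e-9,
        high_freq=spec.frequencies[-1] + spec.freq_resolution,
    )


@pytest.fixture(scope="session")
def moan_call():
    """A synthetic Moan embedded in silence, with its spectrogram."""
    from sealvoc.synth import synth_call

    w, truth = synth_call("Moan", seed=7, sample_rate=SR)
    pad = np.zeros(SR // 2)
    x = np.concatenate([pad, w, pad])
    spec = compute_spectrogram(x, SR, SpectrogramConfig(SR))
    sel = Selection(0.5, 0.5 + truth["duration"], 20.0, 1000.0)
    return x, spec, sel, truth


@pytest.fixture(scope="session")
def feature_matrix():
    """Feature draws at the published class sizes (shared across tests)."""
    from sealvoc.synth import synth_feature_matrix

    return synth_feature_matrix(seed=0)


@pytest.fixture(scope="session")
def loocv_report(feature_matrix):
    from sealvoc.classify import loocv_classify

    X, y = feature_matrix
    return loocv_classify(X, y)


def make_annotations(spans, site="A", label="Growl", **kw):
    """CallAnnotations at (start_s, end_s) offsets from a fixed origin."""
    from sealvoc.repertoire import CallAnnotation

    origin = pd.Timestamp("2021-07-01 00:00:00")
    return [
        CallAnnotation(
            site=site,
            start=origin + pd.Timedelta(seconds=s),
            end=origin + pd.Timedelta(seconds=e),
            label=label,
            **kw,
        )
        for s, e in spans
    ]
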