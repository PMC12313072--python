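"""Shared fixtures.

The two session-scoped benchmarks are the expensive artifacts (a couple of
minutes each); everything else is generated fresh and small per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from neurosound import benchmark, features, synth
from neurosound.nnet import HierarchyNet

SEED = 11


@pytest.fixture(scope="session")
def bench_recovery():
    """Noiseless invertible parameter-recovery benchmark (+ noise control)."""
    return benchmark.make_benchmark(SEED, profile="recovery",
                                    noise_control=True)


@pytest.fixture(scope="session")
def bench_gen():
    """Calibrated-noise mini-benchmark with the full generator stack."""
    return benchmark.make_benchmark(SEED, profile="generator",
                                    noise_sd=benchmark.DEFAULT_NOISE_SD)


@pytest.fixture(scope="session")
def small_stimuli():
    """One stimulus per category plus a few extras, 8 s each."""
    return synth.gen_stimulus_set(
        4, {"speech": 2, "animal": 1, "music": 1, "environment": 1}, seed=3)


@pytest.fixture(scope="session")
def small_specs(small_stimuli):
    """Mel spectrograms of both 4-s halves of each small stimulus."""
    specs = []
    for s in small_stimuli:
        for seg in (s.wave[:features.SEGMENT_SAMPLES],
                    s.wave[features.SEGMENT_SAMPLES:]):
            specs.append(features.melspectrogram(seg))
    return specs


@pytest.fixture(scope="session")
def codec_corpus():
    """A varied spectrogram corpus large enough to fit a 256-code book."""
    specs = []
    stims = synth.gen_stimulus_set(
        16, {"speech": 2, "animal": 2, "music": 2, "environment": 2}, seed=21)
    for s in stims:
        for seg in (s.wave[:features.SEGMENT_SAMPLES],
                    s.wave[features.SEGMENT_SAMPLES:]):
            specs.append(features.melspectrogram(seg))
    return specs


@pytest.fixture(scope="session")
def default_net():
    return HierarchyNet(seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
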