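"""Synthetic stimuli and simulated voxel responses.

Generates category-labelled 8-s waveforms (speech-like harmonic stacks,
animal-like chirp trains, music-like note sequences, environment-like shaped
noise) and simulates fMRI voxel time series as noisy linear encodings of
hierarchical stimulus features with a hemodynamic lag, including the
repeated-presentation and two-sound selective-attention designs. Everything
is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import dsp
from .features import LayerFeature, SEGMENT_SAMPLES

CATEGORIES = ("speech", "animal", "music", "environment")
STIM_SECONDS = 8.0
STIM_SAMPLES = int(STIM_SECONDS * dsp.SAMPLE_RATE)
TR = 2.0
PEAK = 0.9
#: default ROI partition emulating a parcellated auditory cortex
DEFAULT_ROIS = ("A1", "LBelt", "MBelt", "PBelt", "RI", "A4", "A5", "TA2")


@dataclass
class SyntheticStimulus:
    id: str
    category: str
    wave: np.ndarray
    rate: int = dsp.SAMPLE_RATE
    duration: float = STIM_SECONDS

    def __post_init__(self):
        self.wave = np.asarray(self.wave, dtype=np.float64)
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if len(self.wave) != int(self.rate * self.duration):
            raise ValueError("waveform length does not match rate x duration")
        if not np.all(np.isfinite(self.wave)):
            raise ValueError("non-finite amplitude")
        if np.max(np.abs(self.wave)) > 1.0:
            raise ValueError("amplitude exceeds 1")


@dataclass
class EncodingModel:
    """Linear voxel encoding of (window-averaged) stimulus features."""

    layer: str
    weights: np.ndarray              # (voxels, feature units)
    lag: float = 0.0                 # hemodynamic delay, s
    noise_sd: float = 0.0
    roi_labels: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("encoding weights must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.roi_labels is None:
            self.roi_labels = np.array(["AC"] * self.weights.shape[0])
        self.roi_labels = np.asarray(self.roi_labels)
        if len(self.roi_labels) != self.weights.shape[0]:
            raise ValueError("one ROI label per voxel required")

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


@dataclass
class VoxelTimeSeries:
    stimulus_id: str
    repetition: int
    volumes: np.ndarray              # (voxels, time points), TR = 2 s
    condition: str = "train"
    times: np.ndarray | None = None  # volume onsets, s from stimulus onset

    def __post_init__(self):
        self.volumes = np.asarray(self.volumes, dtype=np.float64)
        if self.times is None:
            self.times = TR * np.arange(self.volumes.shape[1])
        if self.volumes.shape[1] < 6:
            raise ValueError("time axis must cover at least 0-10 s (6 volumes)")
        hi = 4 if self.condition == "train" else 8
        if not 1 <= self.repetition <= hi:
            raise ValueError(
                f"repetition {self.repetition} out of range for {self.condition}")


@dataclass
class AttentionTrial:
    stim_a: SyntheticStimulus
    stim_b: SyntheticStimulus
    attended: str                    # "a" or "b"
    mixture: np.ndarray
    #: RMS-equalized component waveforms actually summed into the mixture
    components: tuple | None = None

    def __post_init__(self):
        if self.stim_a.category == self.stim_b.category:
            raise ValueError("attention pairs must span two categories")
        if self.attended not in ("a", "b"):
            raise ValueError("attended must be 'a' or 'b'")
        if len(self.mixture) != len(self.stim_a.wave):
            raise ValueError("mixture length must match the components")
        if self.components is not None:
            ra, rb = (np.sqrt(np.mean(c ** 2)) for c in self.components)
            if abs(ra - rb) > 1e-6 * max(ra, rb):
                raise ValueError("component energies not equalized")

    @property
    def id(self) -> str:
        return f"{self.stim_a.id}+{self.stim_b.id}"

    @property
    def attended_stim(self) -> SyntheticStimulus:
        return self.stim_a if self.attended == "a" else self.stim_b

    @property
    def unattended_stim(self) -> SyntheticStimulus:
        return self.stim_b if self.attended == "a" else self.stim_a


# ------------------------------------------------------------ waveform recipes
def _smooth_walk(rng, n, lo, hi, smooth=2000):
    """A slowly varying random trajectory in [lo, hi]."""
    steps = rng.standard_normal(n // smooth + 2)
    walk = np.cumsum(steps)
    walk = np.interp(np.linspace(0, len(walk) - 1, n), np.arange(len(walk)), walk)
    walk = (walk - walk.min()) / max(walk.max() - walk.min(), 1e-9)
    return lo + (hi - lo) * walk


def _speech(rng, n, variant):
    """Harmonic stack with a wandering pitch contour, formant-like band
    emphasis and syllabic amplitude gating."""
    t = np.arange(n) / dsp.SAMPLE_RATE
    base = 95.0 + 130.0 * variant   # speaker-specific register
    f0 = _smooth_walk(rng, n, base, base + 45.0)
    phase = 2 * np.pi * np.cumsum(f0) / dsp.SAMPLE_RATE
    formants = rng.uniform([400, 1200, 2300], [800, 1900, 3000])
    wave = np.zeros(n)
    for h in range(1, 12):
        fh = h * f0.mean()
        gain = sum(np.exp(-0.5 * ((fh - fm) / 250.0) ** 2) for fm in formants)
        wave += (0.15 + gain) / h * np.sin(h * phase)
    gate_rate = rng.uniform(3.0, 5.0)
    gate = 0.5 * (1 + np.sin(2 * np.pi * gate_rate * t + rng.uniform(0, 2 * np.pi)))
    gate = gate ** 1.5
    return wave * gate


def _animal(rng, n, variant):
    """Repeated frequency-swept chirps with decaying envelopes."""
    wave = np.zeros(n)
    n_chirps = rng.integers(8, 16)
    lo = 800.0 * 2.0 ** (2.2 * variant)    # call-specific frequency band
    for _ in range(n_chirps):
        dur = int(rng.uniform(0.1, 0.3) * dsp.SAMPLE_RATE)
        start = rng.integers(0, n - dur)
        f1, f2 = rng.uniform(lo, 1.8 * lo, 2)
        tt = np.arange(dur) / dsp.SAMPLE_RATE
        freq = f1 + (f2 - f1) * tt / tt[-1]
        phase = 2 * np.pi * np.cumsum(freq) / dsp.SAMPLE_RATE
        env = np.exp(-4.0 * tt / tt[-1]) * np.sqrt(
            np.maximum(np.sin(np.pi * tt / tt[-1]), 0.0))
        wave[start:start + dur] += env * np.sin(phase)
    return wave


def _music(rng, n, variant):
    """Discrete harmonic notes from a pentatonic scale on a metric grid."""
    root = 165.0 * 2.0 ** variant          # instrument-specific register
    scale = root * 2.0 ** (np.array([0, 2, 4, 7, 9, 12]) / 12.0)
    wave = np.zeros(n)
    beat = int(0.25 * dsp.SAMPLE_RATE)
    for start in range(0, n - beat, beat):
        if rng.random() < 0.3:
            continue
        f = rng.choice(scale) * rng.choice([1.0, 2.0])
        dur = beat * int(rng.integers(1, 3))
        dur = min(dur, n - start)
        tt = np.arange(dur) / dsp.SAMPLE_RATE
        env = np.minimum(1.0, tt / 0.01) * np.exp(-3.0 * tt)
        note = sum(np.sin(2 * np.pi * h * f * tt) / h for h in range(1, 6))
        wave[start:start + dur] += env * note
    return wave


def _environment(rng, n, variant):
    """Broadband noise with a random multi-peak spectral shape, slow
    amplitude drift and optional rhythmic pulsing.

    Several independent spectral bumps (random center, width and gain) keep
    exemplars of this category mutually distinguishable even after heavy
    spectrogram compression.
    """
    noise = rng.standard_normal(n)
    X = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / dsp.SAMPLE_RATE)
    lf = np.log2(np.maximum(freqs, 20.0))
    tilt = rng.uniform(-1.0, 0.2)
    shape = (np.maximum(freqs, 20.0) / 1000.0) ** tilt
    bumps = np.zeros_like(shape)
    # the dominant bump is placed by the variant; extra bumps are random
    c0 = np.log2(250.0) + variant * (np.log2(7000.0) - np.log2(250.0))
    bumps += 2.0 * np.exp(-0.5 * ((lf - c0) / rng.uniform(0.4, 0.9)) ** 2)
    for _ in range(rng.integers(1, 3)):
        center = rng.uniform(np.log2(200), np.log2(8000))
        width = rng.uniform(0.4, 1.5)
        gain = rng.uniform(0.5, 2.0)
        bumps += gain * np.exp(-0.5 * ((lf - center) / width) ** 2)
    wave = np.fft.irfft(X * shape * bumps, n=n)
    env = _smooth_walk(rng, n, 0.4, 1.0, smooth=8000)
    if rng.random() < 0.5:  # some environmental sounds pulse (rain, engine)
        rate = rng.uniform(1.0, 8.0)
        t = np.arange(n) / dsp.SAMPLE_RATE
        depth = rng.uniform(0.2, 0.8)
        env = env * (1.0 - depth + depth *
                     0.5 * (1 + np.sin(2 * np.pi * rate * t)))
    return wave * env


_RECIPES = {"speech": _speech, "animal": _animal,
            "music": _music, "environment": _environment}


def make_stimulus(category: str, seed: int, stim_id: str | None = None,
                  duration: float = STIM_SECONDS,
                  variant: float | None = None) -> SyntheticStimulus:
    """One peak-normalized stimulus of the given category, pure in its seed.

    ``variant`` in [0, 1) sets the recipe's primary exemplar parameter
    (register, frequency band, spectral peak); None draws it from the seed.
    Test sets stratify the variant so exemplars of one category stay
    mutually identifiable, emulating the curation of recognizable stimuli.
    """
    if category not in _RECIPES:
        raise ValueError(f"unknown category {category!r}")
    rng = np.random.default_rng(seed)
    if variant is None:
        variant = float(rng.random())
    n = int(duration * dsp.SAMPLE_RATE)
    wave = _RECIPES[category](rng, n, variant)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave = PEAK * wave / peak
    return SyntheticStimulus(id=stim_id or f"{category}_{seed}",
                             category=category, wave=wave, duration=duration)


def gen_stimulus_set(n_train: int, n_test_per_category: dict[str, int],
                     seed: int) -> list[SyntheticStimulus]:
    """Training stimuli with mixed category content plus single-category
    test stimuli; deterministic given the seed.

    The full-scale design is ``n_train=1200`` with test counts
    ``{speech: 20, animal: 10, music: 10, environment: 10}`` (1,250 total).
    """
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    for cat, cnt in n_test_per_category.items():
        if cat not in CATEGORIES:
            raise ValueError(f"unknown category {cat!r}")
        if cnt < 1:
            raise ValueError(f"test count for {cat!r} must be >= 1")
    rng = np.random.default_rng(seed)
    stimuli = []
    cats = rng.choice(CATEGORIES, size=n_train)
    for i in range(n_train):
        stimuli.append(make_stimulus(cats[i], int(rng.integers(2 ** 31)),
                                     stim_id=f"train_{i:04d}"))
    for cat in CATEGORIES:  # fixed order, independent of dict ordering
        m = n_test_per_category.get(cat, 0)
        for j in range(m):
            stimuli.append(make_stimulus(cat, int(rng.integers(2 ** 31)),
                                         stim_id=f"test_{cat}_{j:02d}",
                                         variant=(j + 0.5) / m))
    return stimuli


# -------------------------------------------------------------- encoding model
def make_encoding_model(n_units: int, layer: str = "L5", n_voxels: int = 800,
                        noise_sd: float = 0.0, lag: float = 0.0, seed: int = 0,
                        rois: Sequence[str] = DEFAULT_ROIS,
                        sparsity: float = 0.5) -> EncodingModel:
    """Random Gaussian encoding weights with per-ROI sparsity masks.

    Voxels are partitioned into ``rois`` by contiguous index blocks; each ROI
    zeroes a seeded random subset of feature units so regions differ without
    implying any hierarchy.
    """
    rng = np.random.default_rng(seed)
    w = rng.normal(0.0, 1.0 / np.sqrt(n_units), (n_voxels, n_units))
    labels = np.empty(n_voxels, dtype=object)
    blocks = np.array_split(np.arange(n_voxels), len(rois))
    for roi, idx in zip(rois, blocks):
        labels[idx] = roi
        mask = rng.random(n_units) >= sparsity
        if not mask.any():
            mask[rng.integers(n_units)] = True
        w[idx] *= mask
    return EncodingModel(layer=layer, weights=w, lag=lag, noise_sd=noise_sd,
                         roi_labels=labels.astype(str), seed=seed)


def window_features(stim_wave: np.ndarray, onset: float,
                    features_fn: Callable[[np.ndarray], LayerFeature]) -> np.ndarray:
    """Window-averaged feature vector of the 4-s content [onset, onset+4),
    zero-padded outside the stimulus extent."""
    seg = np.zeros(SEGMENT_SAMPLES)
    i0 = int(round(onset * dsp.SAMPLE_RATE))
    lo, hi = max(i0, 0), min(i0 + SEGMENT_SAMPLES, len(stim_wave))
    if hi > lo:
        seg[lo - i0: hi - i0] = stim_wave[lo:hi]
    feat = features_fn(seg)
    return feat.values.mean(axis=1)


def simulate_fmri(stimuli: Sequence[SyntheticStimulus], model: EncodingModel,
                  features_fn: Callable[[np.ndarray], LayerFeature],
                  n_reps: int, seed: int, condition: str = "train",
                  n_volumes: int = 6) -> list[VoxelTimeSeries]:
    """Simulate voxel volumes for each stimulus and repetition.

    The volume at time ``t`` equals ``weights @ u`` plus Gaussian noise,
    where ``u`` is the window-averaged feature vector of the stimulus content
    in ``[t - lag - 4, t - lag)``. Noise is independent across repetitions
    and voxels; the whole simulation is deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = []
    times = TR * np.arange(n_volumes)
    for stim in stimuli:
        u = np.stack([window_features(stim.wave, t - model.lag - 4.0, features_fn)
                      for t in times], axis=1)   # (units, n_volumes)
        if u.shape[0] != model.weights.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: model weights are "
                f"{model.weights.shape} but features have {u.shape[0]} units")
        clean = model.weights @ u
        for rep in range(1, n_reps + 1):
            noise = model.noise_sd * rng.standard_normal(clean.shape)
            out.append(VoxelTimeSeries(stimulus_id=stim.id, repetition=rep,
                                       volumes=clean + noise,
                                       condition=condition, times=times.copy()))
    return out


# ----------------------------------------------------------- attention design
def make_attention_design(test_pool: Sequence[SyntheticStimulus],
                          n_pairs: int | None = None,
                          seed: int = 0) -> list[AttentionTrial]:
    """Cross-category superimposed pairs, each under both attention conditions.

    ``n_pairs=None`` enumerates every cross-category combination (the
    full-scale pool of two exemplars per category yields 24 pairs and 48
    trials); an integer subsamples that enumeration.
    """
    cats = {s.category for s in test_pool}
    if len(cats) < 2:
        raise ValueError("attention design needs stimuli from >= 2 categories")
    pairs = [(a, b) for i, a in enumerate(test_pool)
             for b in test_pool[i + 1:] if a.category != b.category]
    rng = np.random.default_rng(seed)
    if n_pairs is not None:
        if n_pairs > len(pairs):
            raise ValueError(f"requested {n_pairs} pairs but only "
                             f"{len(pairs)} cross-category pairs exist")
        idx = rng.choice(len(pairs), size=n_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    trials = []
    for a, b in pairs:
        mixture, comps = mix_waves(a.wave, b.wave)
        for attended in ("a", "b"):
            trials.append(AttentionTrial(stim_a=a, stim_b=b, attended=attended,
                                         mixture=mixture, components=comps))
    return trials


def mix_waves(wa: np.ndarray, wb: np.ndarray):
    """RMS-equalize two components, sum, and peak-normalize the mixture.

    Returns (mixture, (component_a, component_b)) with the components scaled
    to equal RMS as summed.
    """
    target = np.sqrt(np.mean(wa ** 2))
    wb_scaled = wb * target / max(np.sqrt(np.mean(wb ** 2)), 1e-12)
    mix = wa + wb_scaled
    peak = np.max(np.abs(mix))
    if peak > 0:
        mix = PEAK * mix / peak
    return mix, (wa, wb_scaled)


def simulate_attention(trials: Sequence[AttentionTrial], model: EncodingModel,
                       features_fn: Callable[[np.ndarray], LayerFeature],
                       n_reps: int, seed: int,
                       unattended_leak: float = 0.3) -> list[VoxelTimeSeries]:
    """Voxel responses in the two-sound attention task.

    Each trial's response encodes the attended component's features plus a
    ``unattended_leak`` fraction of the unattended component's, modelling
    partial attentional selection, with the same lag/noise conventions as
    :func:`simulate_fmri`. Series are keyed ``<pair id>#<attended>``.
    """
    rng = np.random.default_rng(seed)
    out = []
    n_volumes = 6
    times = TR * np.arange(n_volumes)
    for trial in trials:
        ua = np.stack([window_features(trial.attended_stim.wave,
                                       t - model.lag - 4.0, features_fn)
                       for t in times], axis=1)
        uu = np.stack([window_features(trial.unattended_stim.wave,
                                       t - model.lag - 4.0, features_fn)
                       for t in times], axis=1)
        clean = model.weights @ (ua + unattended_leak * uu)
        for rep in range(1, n_reps + 1):
            noise = model.noise_sd * rng.standard_normal(clean.shape)
            out.append(VoxelTimeSeries(
                stimulus_id=f"{trial.id}#{trial.attended}", repetition=rep,
                volumes=clean + noise, condition="attention",
                times=times.copy()))
    return out
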