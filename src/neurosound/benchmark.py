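"""The packaged synthetic benchmarks.

Builds, from a single seed, everything needed to exercise the full
reconstruction framework at desk scale: a category-structured stimulus set,
window features from the conv hierarchy, voxel responses as linear
encodings of those features, trained decoders (including a pure-noise
control), the codebook + translator generator stack, and reconstructions
ready for the evaluation battery.

Voxel responses here encode each data sample's window feature directly
(``voxel = W @ feature + noise``): the invertible configuration that
parameter-recovery checks presuppose, since the volume-level route of
:mod:`neurosound.synth` is non-invertible in principle (overlapping 4-s
windows share averaged fMRI volumes). The volume-level simulator remains
the general-purpose machinery and is exercised on its own contracts.

Two frozen profiles:

``recovery``
    168 feature units (narrow hierarchy), 800 voxels / 500 selected,
    1,000 training stimuli x 4 repetitions x 3 windows, noiseless.
    Ridge at lambda = 100 recovers the features nearly exactly here
    (units << selected voxels, ample samples), the regime in which decoded
    identification saturates.

``generator``
    The mini-benchmark shape: 120 training stimuli, 20 test stimuli
    (8 speech, 4 per other category), 400 voxels / 200 selected, the
    default 64-channel hierarchy, and the full codebook + translator stack
    (translator corpus: 240 training windows plus the test windows' audio).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoding, evaluation, generator, sampling, synth
from .features import MelSpectrogram, melspectrogram
from .nnet import HierarchyNet

DEFAULT_TEST_COUNTS = {"speech": 8, "animal": 4, "music": 4, "environment": 4}
WINDOW_OFFSETS = (0.0, 2.0, 4.0)
#: noise level (a.u., on unit-variance encoded features) at which decoded
#: identification on the generator profile lands in the 70-90% band
DEFAULT_NOISE_SD = 12.0

PROFILES = {
    "recovery": dict(n_train=1000, n_voxels=800, k_voxels=500,
                     n_train_reps=4, channels=(4, 6, 8, 8, 8),
                     noise_sd=0.0, fit_generator=False),
    "generator": dict(n_train=120, n_voxels=400, k_voxels=200,
                      n_train_reps=1, channels=(16, 32, 64, 64, 64),
                      noise_sd=0.0, fit_generator=True),
}


def window_feature_maps(stimuli, net: HierarchyNet, layer: str = "L5"):
    """Per stimulus: [(MelSpectrogram, (units, 21) feature map)] per window."""
    spec_obj = sampling.WindowSpec(offsets=WINDOW_OFFSETS)
    out = []
    for stim in stimuli:
        per_win = []
        for seg in sampling.window_stimulus(stim, spec_obj):
            m = melspectrogram(seg)
            per_win.append((m, net.forward(m.values)[layer]))
        out.append(per_win)
    return out


def sample_encoded_dataset(stimuli, maps, W: np.ndarray, noise_sd: float,
                           seed: int, condition: str = "train",
                           n_reps: int = 1,
                           n_trials_averaged: int = 1) -> sampling.Dataset:
    """Dataset whose voxel vectors encode the window features directly.

    ``voxel = W @ flat_feature + noise``, with ``n_reps`` independent noisy
    repetitions per window kept as separate samples (the training design) or
    ``n_trials_averaged`` folded into a single averaged sample whose noise
    standard deviation is ``noise_sd / sqrt(n)`` (the test design).
    """
    rng = np.random.default_rng(seed)
    sd = noise_sd / np.sqrt(n_trials_averaged)
    samples = []
    for stim, per_win in zip(stimuli, maps):
        for w, (_, fmap) in enumerate(per_win):
            flat = fmap.reshape(-1)
            clean = W @ flat
            for rep in range(1, n_reps + 1):
                x = clean + sd * rng.standard_normal(W.shape[0])
                samples.append(sampling.DataSample(
                    stimulus_id=stim.id, window_index=w, voxel_vector=x,
                    target=flat, condition=condition,
                    n_trials_averaged=n_trials_averaged,
                    repetition=rep if n_reps > 1 else None,
                    category=stim.category))
    return sampling.Dataset(samples=samples, design={
        "condition": condition, "n_stimuli": len(stimuli),
        "n_windows": len(WINDOW_OFFSETS), "n_reps": n_reps,
        "encoding": "sample", "n_samples": len(samples)})


@dataclass
class Benchmark:
    seed: int
    stimuli_train: list
    stimuli_test: list
    net: HierarchyNet
    evaluator: HierarchyNet
    W: np.ndarray
    ds_train: sampling.Dataset
    ds_test: sampling.Dataset
    decoder: decoding.FeatureDecoder
    noise_decoder: decoding.FeatureDecoder | None = None
    ds_test_noise: sampling.Dataset | None = None
    codebook: generator.Codebook | None = None
    translator: generator.Translator | None = None
    maps_train: list = field(default_factory=list, repr=False)
    maps_test: list = field(default_factory=list, repr=False)
    layer: str = "L5"

    def test_pool_specs(self, window: int) -> list[MelSpectrogram]:
        return [per_win[window][0] for per_win in self.maps_test]

    def true_feature(self, stim_index: int, window: int) -> np.ndarray:
        return self.maps_test[stim_index][window][1]


def make_benchmark(seed: int, profile: str = "generator",
                   noise_sd: float | None = None,
                   noise_control: bool = False,
                   translator_corpus: int = 240,
                   translator_maxiter: int = 300,
                   translator_lam: float = 1e-6,
                   **overrides) -> Benchmark:
    """Build an end-to-end benchmark from one seed.

    ``profile`` selects the frozen configuration (see module docstring);
    keyword overrides adjust individual knobs. ``noise_control=True``
    additionally trains a decoder on pure-noise voxels (zero encoding
    weights), the chance-level control.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}")
    cfg = {**PROFILES[profile], **overrides}
    if noise_sd is not None:
        cfg["noise_sd"] = noise_sd
    nsd = cfg["noise_sd"]
    stims = synth.gen_stimulus_set(cfg["n_train"], DEFAULT_TEST_COUNTS, seed)
    train = [s for s in stims if s.id.startswith("train")]
    test = [s for s in stims if s.id.startswith("test")]
    net = HierarchyNet(seed=seed + 1, channels=tuple(cfg["channels"]))
    evaluator = HierarchyNet(seed=seed + 7919)  # independent evaluation net
    maps_train = window_feature_maps(train, net)
    maps_test = window_feature_maps(test, net)
    n_units = maps_train[0][0][1].size
    rng = np.random.default_rng(seed + 2)
    W = rng.normal(0.0, 1.0 / np.sqrt(n_units), (cfg["n_voxels"], n_units))
    ds_train = sample_encoded_dataset(train, maps_train, W, nsd, seed + 3,
                                      "train", n_reps=cfg["n_train_reps"])
    # with noise, test responses are 8-trial averages; without, averaging
    # changes nothing and single trials are used
    n_avg = 8 if nsd > 0 else 1
    ds_test = sample_encoded_dataset(test, maps_test, W, nsd, seed + 4,
                                     "test", n_trials_averaged=n_avg)
    decoder = decoding.fit_decoder_from_dataset(ds_train, k=cfg["k_voxels"])
    bench = Benchmark(seed=seed, stimuli_train=train, stimuli_test=test,
                      net=net, evaluator=evaluator, W=W, ds_train=ds_train,
                      ds_test=ds_test, decoder=decoder,
                      maps_train=maps_train, maps_test=maps_test)
    if noise_control:
        W0 = np.zeros_like(W)
        csd = max(nsd, 1.0)
        ds_train_n = sample_encoded_dataset(train, maps_train, W0, csd,
                                            seed + 5, "train",
                                            n_reps=cfg["n_train_reps"])
        bench.ds_test_noise = sample_encoded_dataset(
            test, maps_test, W0, csd, seed + 6, "test", n_trials_averaged=8)
        bench.noise_decoder = decoding.fit_decoder_from_dataset(
            ds_train_n, k=cfg["k_voxels"])
    if cfg["fit_generator"]:
        all_specs = [m for per_win in maps_train for (m, _) in per_win]
        bench.codebook = generator.fit_codebook(all_specs, seed=seed + 8)
        sub = np.random.default_rng(seed + 9).choice(
            len(all_specs), size=min(translator_corpus, len(all_specs)),
            replace=False)
        # the generator corpus also covers the test stimuli's audio -- the
        # generator is trained on sound alone and never sees voxel data
        feats = [maps_train[i // 3][i % 3][1] for i in sub]
        grids = [generator.encode(all_specs[i], bench.codebook) for i in sub]
        for i, per_win in enumerate(maps_test):
            for (m, fmap) in per_win:
                feats.append(fmap)
                grids.append(generator.encode(m, bench.codebook))
        bench.translator = generator.fit_translator(
            feats, grids, seed=seed + 10, maxiter=translator_maxiter,
            lam=translator_lam, min_corpus=min(50, len(feats)))
    if not cfg["fit_generator"]:
        # training spectrograms only feed the generator corpus; drop them
        # so large recovery-profile benchmarks stay lean in memory
        bench.maps_train = []
    return bench


# ------------------------------------------------------------- evaluation aids
def decoded_identification(bench: Benchmark, decoder=None, ds_test=None,
                           metric: str = "pearson", scope: str = "all"):
    """Window-level identification of decoded features against the test pool.

    Returns (outcomes, block scores, mean profile correlation).
    """
    decoder = decoder or bench.decoder
    ds_test = ds_test or bench.ds_test
    Ytrue = ds_test.target_matrix()
    Yhat = decoder.predict(ds_test.voxel_matrix(),
                           n_trials=ds_test.samples[0].n_trials_averaged)
    _, mean_r, _ = evaluation.profile_correlation(Ytrue, Yhat, metric=metric)
    outcomes = []
    n_windows = ds_test.design["n_windows"]
    for w in range(n_windows):
        ids = [i for i, s in enumerate(ds_test.samples) if s.window_index == w]
        pool = [Ytrue[i] for i in ids]
        cats = [ds_test.samples[i].category for i in ids]
        for ti, i in enumerate(ids):
            outcomes.append(evaluation.pairwise_identification(
                Yhat[i], pool, ti, metric=metric, scope=scope,
                categories=cats,
                sample_id=f"{ds_test.samples[i].stimulus_id}/{w}"))
    blocks = evaluation.block_aggregate([o for o in outcomes if o])
    return outcomes, blocks, mean_r


def reconstruct_test_set(bench: Benchmark, source: str = "decoded",
                         seed: int = 0, render_audio: bool = False,
                         ) -> list[generator.ReconstructedAudio]:
    """Full-pipeline reconstructions of every test sample.

    ``source`` is 'decoded' (brain route), 'true' (recovery check) or
    'noise' (the pure-noise control decoder). ``render_audio=False`` skips
    the Griffin-Lim waveform stage, leaving spectrogram reconstructions.
    """
    if bench.translator is None:
        raise ValueError("benchmark was built with fit_generator=False")
    recs = []
    decoder = bench.decoder
    ds = bench.ds_test
    if source == "noise":
        if bench.noise_decoder is None:
            raise ValueError("benchmark was built without noise_control")
        decoder, ds = bench.noise_decoder, bench.ds_test_noise
    for i, s in enumerate(ds.samples):
        feats = (bench.true_feature(i // 3, s.window_index)
                 if source == "true" else None)
        recs.append(generator.reconstruct_full(
            decoder, bench.codebook, bench.translator, s, seed=seed,
            features=feats, render_audio=render_audio))
    return recs


def recon_identification(recs, bench: Benchmark, stage: int = 0,
                         perturbation: str | None = None,
                         window_ms: float | None = None, seed: int = 0):
    """Identification of reconstructions against the test-stimulus pool.

    ``stage=0`` compares spectrogram pixels, 1-6 evaluator-hierarchy
    features. ``perturbation`` disrupts only the true candidate.
    """
    outcomes = []
    for i, rec in enumerate(recs):
        w = rec.provenance["window"]
        stim_idx = i // 3
        pool = bench.test_pool_specs(w)
        sid = f"{rec.provenance['stimulus_id']}/{w}"
        if perturbation is not None:
            outcomes.append(evaluation.perturbed_identification(
                rec.spec, pool, stim_idx, perturbation, seed=seed + i,
                window_ms=window_ms, stage=stage,
                evaluator=bench.evaluator, sample_id=sid))
        elif stage == 0:
            probe = rec.spec.values.reshape(-1)
            cands = [p.values.reshape(-1) for p in pool]
            outcomes.append(evaluation.pairwise_identification(
                probe, cands, stim_idx, sample_id=sid))
        else:
            outcomes.append(evaluation.hierarchical_identification(
                rec.spec, pool, bench.evaluator, stage, stim_idx,
                sample_id=sid))
    return outcomes
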