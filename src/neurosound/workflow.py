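"""Command implementations behind the CLI.

Each stage reads and writes documented artifacts inside the run directory
(WAV + CSV manifests for stimuli, HDF5 for datasets and models, CSV/JSON
for results) and emits structured JSON log lines, so a run is inspectable
and resumable stage by stage.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import benchmark, decoding, evaluation, generator, io, synth
from .config import RunConfig
from .features import LayerFeature, acoustic_summary, melspectrogram
from .nnet import HierarchyNet


def log(stage: str, **fields):
    print(json.dumps({"stage": stage, "time": round(time.time(), 2), **fields}))


def _outdir(cfg: RunConfig) -> Path:
    d = Path(cfg.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def _meta(cfg: RunConfig) -> dict:
    return {"config_hash": io.config_hash(cfg.to_dict()), "seed": cfg.seed}


def _load_stimuli(cfg: RunConfig):
    d = _outdir(cfg) / "stimuli"
    manifest = d / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(
            f"no stimuli at {d}; run the 'simulate' command first")
    rows = pd.read_csv(manifest)
    stims = []
    for _, row in rows.iterrows():
        wave, rate = io.read_wav(d / f"{row['id']}.wav")
        stims.append(synth.SyntheticStimulus(
            id=row["id"], category=row["category"], wave=wave, rate=rate,
            duration=row["duration"]))
    return stims


def _net(cfg: RunConfig) -> HierarchyNet:
    return HierarchyNet(seed=cfg.stage_seed(1), channels=tuple(cfg.channels))


def _maps(cfg: RunConfig, stims):
    return benchmark.window_feature_maps(stims, _net(cfg), cfg.layer)


def _split(stims):
    return ([s for s in stims if s.id.startswith("train")],
            [s for s in stims if s.id.startswith("test")])


def run_simulate(cfg: RunConfig):
    """Generate stimuli, simulate encoded responses, write datasets."""
    d = _outdir(cfg)
    stims = synth.gen_stimulus_set(cfg.n_train, cfg.test_counts, cfg.seed)
    io.write_stimuli(d / "stimuli", stims, seed=cfg.seed)
    train, test = _split(stims)
    maps_train = _maps(cfg, train)
    maps_test = _maps(cfg, test)
    n_units = maps_train[0][0][1].size
    rng = np.random.default_rng(cfg.stage_seed(2))
    W = rng.normal(0.0, 1.0 / np.sqrt(n_units), (cfg.n_voxels, n_units))
    np.save(d / "encoding_weights.npy", W)
    ds_train = benchmark.sample_encoded_dataset(
        train, maps_train, W, cfg.noise_sd, cfg.stage_seed(3), "train",
        n_reps=cfg.n_train_reps)
    n_avg = 8 if cfg.noise_sd > 0 else 1
    ds_test = benchmark.sample_encoded_dataset(
        test, maps_test, W, cfg.noise_sd, cfg.stage_seed(4), "test",
        n_trials_averaged=n_avg)
    io.write_dataset(d / "dataset_train.h5", ds_train)
    io.write_dataset(d / "dataset_test.h5", ds_test)
    cfg.save(d / "config.yaml")
    log("simulate", n_train_samples=len(ds_train), n_test_samples=len(ds_test),
        n_stimuli=len(stims), **_meta(cfg))


def run_features(cfg: RunConfig):
    """Acoustic descriptors of the test stimuli (F0 / SC / HNR) to CSV."""
    d = _outdir(cfg)
    _, test = _split(_load_stimuli(cfg))
    rows = []
    for s in test:
        a = acoustic_summary(s.wave)
        rows.append((s.id, s.category, a.f0_mean, a.sc_median, a.hnr_mean))
    df = pd.DataFrame(rows, columns=["id", "category", "f0_mean",
                                     "sc_median", "hnr_mean"])
    df.to_csv(d / "acoustic_features.csv", index=False)
    log("features", n_stimuli=len(df),
        n_undefined_f0=int(df.f0_mean.isna().sum()), **_meta(cfg))


def run_train_decoder(cfg: RunConfig):
    d = _outdir(cfg)
    path = d / "dataset_train.h5"
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the 'simulate' command first")
    ds_train = io.read_dataset(path)
    dec = decoding.fit_decoder_from_dataset(ds_train, k=cfg.k_voxels,
                                            layer=cfg.layer)
    io.write_decoder(d / "decoder.h5", dec, extra_meta=_meta(cfg))
    if cfg.pipeline == "brain_to_codebook":
        # decode the continuous patch-space representation directly
        train, _ = _split(_load_stimuli(cfg))
        maps_train = _maps(cfg, train)
        specs, X = [], []
        by_key = {}
        for i, s in enumerate(ds_train.samples):
            by_key.setdefault((s.stimulus_id, s.window_index),
                              []).append(s.voxel_vector)
        for j, stim in enumerate(train):
            for w in range(3):
                specs.append(maps_train[j][w][0])
                X.append(np.mean(by_key[(stim.id, w)], axis=0))
        dec_cb = generator.fit_codebook_decoder(np.stack(X), specs,
                                                k=cfg.k_voxels)
        io.write_decoder(d / "decoder_patches.h5", dec_cb,
                         extra_meta=_meta(cfg))
    if cfg.pipeline == "pixel_opt":
        # one decoder per hierarchy layer, targets pooled to 21 columns
        from .features import LayerFeature, temporal_downsample
        train, _ = _split(_load_stimuli(cfg))
        net = _net(cfg)
        X = ds_train.voxel_matrix()
        keys = [(s.stimulus_id, s.window_index) for s in ds_train.samples]
        import neurosound.sampling as sampling_mod
        for layer in ("L1", "L2", "L3", "L4", "L5", "FC"):
            targets = {}
            for j, stim in enumerate(train):
                segs = sampling_mod.window_stimulus(stim)
                for w, seg in enumerate(segs):
                    acts = net.forward(melspectrogram(seg).values)[layer]
                    targets[(stim.id, w)] = temporal_downsample(
                        LayerFeature(layer, acts)).reshape(-1)
            Y = np.stack([targets[k] for k in keys])
            dl = decoding.fit_decoder(X, Y, k=cfg.k_voxels, layer=layer)
            io.write_decoder(d / f"decoder_{layer}.h5", dl,
                             extra_meta=_meta(cfg))
    log("train-decoder", n_samples=len(ds_train),
        n_voxels_selected=len(dec.voxel_indices), lam=dec.lam,
        pipeline=cfg.pipeline, **_meta(cfg))


def run_train_generator(cfg: RunConfig):
    d = _outdir(cfg)
    stims = _load_stimuli(cfg)
    train, test = _split(stims)
    maps_train = _maps(cfg, train)
    maps_test = _maps(cfg, test)
    all_specs = [m for pw in maps_train for (m, _) in pw]
    cb = generator.fit_codebook(all_specs, seed=cfg.stage_seed(8))
    sub = np.random.default_rng(cfg.stage_seed(9)).choice(
        len(all_specs), size=min(cfg.translator_corpus, len(all_specs)),
        replace=False)
    feats = [maps_train[i // 3][i % 3][1] for i in sub]
    grids = [generator.encode(all_specs[i], cb) for i in sub]
    for per_win in maps_test:
        for (m, fmap) in per_win:
            feats.append(fmap)
            grids.append(generator.encode(m, cb))
    tr = generator.fit_translator(feats, grids, seed=cfg.stage_seed(10),
                                  layer=cfg.layer, maxiter=300, lam=1e-6,
                                  min_corpus=min(50, len(feats)))
    io.write_codebook(d / "codebook.h5", cb)
    io.write_translator(d / "translator.h5", tr)
    log("train-generator", corpus=len(feats),
        final_loss=float(tr.loss_trace[-1]), **_meta(cfg))


def run_reconstruct(cfg: RunConfig):
    d = _outdir(cfg)
    needed = {"dataset_test.h5": "simulate"}
    if cfg.pipeline == "full":
        needed.update({"decoder.h5": "train-decoder",
                       "codebook.h5": "train-generator",
                       "translator.h5": "train-generator"})
    elif cfg.pipeline == "brain_to_codebook":
        needed.update({"decoder_patches.h5": "train-decoder",
                       "codebook.h5": "train-generator"})
    elif cfg.pipeline == "pixel_opt":
        needed.update({f"decoder_{l}.h5": "train-decoder"
                       for l in ("L1", "L2", "L3", "L4", "L5", "FC")})
    else:
        raise ValueError(f"unknown pipeline {cfg.pipeline!r}")
    for name, producer in needed.items():
        if not (d / name).exists():
            raise FileNotFoundError(
                f"missing {d / name}; run the '{producer}' command first")
    ds_test = io.read_dataset(d / "dataset_test.h5")
    rec_dir = d / "reconstructions"
    rec_dir.mkdir(exist_ok=True)
    prov = []
    if cfg.pipeline == "full":
        dec = io.read_decoder(d / "decoder.h5")
        cb = io.read_codebook(d / "codebook.h5")
        tr = io.read_translator(d / "translator.h5")
        make = lambda s: generator.reconstruct_full(
            dec, cb, tr, s, seed=cfg.stage_seed(20),
            render_audio=cfg.render_audio)
    elif cfg.pipeline == "brain_to_codebook":
        dec_cb = io.read_decoder(d / "decoder_patches.h5")
        cb = io.read_codebook(d / "codebook.h5")
        make = lambda s: generator.reconstruct_brain_to_codebook(
            dec_cb, cb, s, seed=cfg.stage_seed(20),
            render_audio=cfg.render_audio)
    else:
        decs = {l: io.read_decoder(d / f"decoder_{l}.h5")
                for l in ("L1", "L2", "L3", "L4", "L5", "FC")}
        net = _net(cfg)

        def make(s):
            from .nnet import LAYER_TEMPORAL
            targets = {}
            for layer, dl in decs.items():
                cols = dl.predict_matched(s.voxel_vector,
                                          n_trials=s.n_trials_averaged)
                cols = cols.reshape(-1, 21)
                # expand the 21 decoded columns to the layer's native
                # temporal length by piecewise-constant repetition
                reps = max(1, LAYER_TEMPORAL[layer] // 21)
                full = np.repeat(cols, reps, axis=1)[:, :LAYER_TEMPORAL[layer]]
                targets[layer] = full
            spec, trace = generator.pixel_optimize(
                targets, net, seed=cfg.stage_seed(20))
            wave = (generator.invert_spectrogram(spec,
                                                 seed=cfg.stage_seed(20))
                    if cfg.render_audio else None)
            return generator.ReconstructedAudio(
                wave=wave, spec=spec, provenance={
                    "pipeline": "pixel_opt",
                    "stimulus_id": s.stimulus_id,
                    "window": s.window_index, "final_loss": float(trace[-1]),
                    "seed": cfg.stage_seed(20)})
    for s in ds_test.samples:
        rec = make(s)
        name = f"{s.stimulus_id}_w{s.window_index}"
        if rec.wave is not None:
            io.write_wav(rec_dir / f"{name}.wav", rec.wave)
        np.save(rec_dir / f"{name}_spec.npy", rec.spec.values)
        prov.append({**rec.provenance, **_meta(cfg)})
    (rec_dir / "provenance.json").write_text(json.dumps(prov, indent=1))
    log("reconstruct", n=len(prov), pipeline=cfg.pipeline, **_meta(cfg))


def run_evaluate(cfg: RunConfig):
    d = _outdir(cfg)
    dec = io.read_decoder(d / "decoder.h5")
    ds_test = io.read_dataset(d / "dataset_test.h5")
    Ytrue = ds_test.target_matrix()
    Yhat = dec.predict(ds_test.voxel_matrix(),
                       n_trials=ds_test.samples[0].n_trials_averaged)
    _, mean_r, n_const = evaluation.profile_correlation(
        Ytrue, Yhat, metric=cfg.metric if cfg.metric != "euclidean" else "pearson")
    outcomes = []
    for w in range(ds_test.design["n_windows"]):
        ids = [i for i, s in enumerate(ds_test.samples)
               if s.window_index == w]
        pool = [Ytrue[i] for i in ids]
        cats = [ds_test.samples[i].category for i in ids]
        for ti, i in enumerate(ids):
            outcomes.append(evaluation.pairwise_identification(
                Yhat[i], pool, ti, metric=cfg.metric, scope=cfg.scope,
                categories=cats,
                sample_id=f"{ds_test.samples[i].stimulus_id}/{w}"))
    blocks = evaluation.block_aggregate([o for o in outcomes if o])
    stat = evaluation.ci95([b.accuracy for b in blocks])
    evaluation.outcomes_table(outcomes).to_csv(d / "identification.csv",
                                               index=False)
    summary = {"profile_correlation_mean": mean_r,
               "n_constant_units": n_const,
               "block_accuracy_mean": stat.mean,
               "block_accuracy_ci95": [stat.ci95_low, stat.ci95_high],
               "n_blocks": len(blocks), "metric": cfg.metric,
               "scope": cfg.scope, **_meta(cfg)}
    (d / "evaluation.json").write_text(json.dumps(summary, indent=1))
    log("evaluate", **summary)


def run_attention(cfg: RunConfig):
    """Two-sound attention battery at the decoded-feature level."""
    d = _outdir(cfg)
    dec = io.read_decoder(d / "decoder.h5")
    stims = _load_stimuli(cfg)
    _, test = _split(stims)
    # pool: n exemplars per category, excluding none (environment included
    # at this desk scale), all cross-category combinations
    pool = []
    for cat in synth.CATEGORIES:
        pool.extend([s for s in test if s.category == cat]
                    [: cfg.n_attention_exemplars])
    trials = synth.make_attention_design(pool, seed=cfg.stage_seed(30))
    net = _net(cfg)
    W = np.load(d / "encoding_weights.npy")
    rng = np.random.default_rng(cfg.stage_seed(31))
    window_scores = {}
    for t_i, trial in enumerate(trials):
        att_maps = benchmark.window_feature_maps([trial.attended_stim], net,
                                                 cfg.layer)[0]
        una_maps = benchmark.window_feature_maps([trial.unattended_stim], net,
                                                 cfg.layer)[0]
        scores = []
        for w in range(3):
            ua = att_maps[w][1].reshape(-1)
            uu = una_maps[w][1].reshape(-1)
            x = W @ (ua + cfg.attention_leak * uu) + \
                (cfg.noise_sd / np.sqrt(8)) * rng.standard_normal(W.shape[0])
            yhat = dec.predict_matched(x, n_trials=8)
            scores.append(evaluation.attention_window_score(
                yhat, ua, uu, metric=cfg.metric))
        window_scores[f"{trial.id}#{trial.attended}"] = scores
    outcomes, stat = evaluation.attention_evaluate(window_scores)
    rows = [(o.trial_id, int(o.correct)) for o in outcomes]
    pd.DataFrame(rows, columns=["trial_id", "correct"]).to_csv(
        d / "attention.csv", index=False)
    summary = {"n_trials": len(outcomes), "accuracy": stat.mean,
               "binomial_p": stat.p_value, **_meta(cfg)}
    (d / "attention.json").write_text(json.dumps(summary, indent=1))
    log("attention", **summary)


def run_power(cfg: RunConfig):
    """The two prospective sample-size computations."""
    n_t = evaluation.required_n_ttest(d=0.5, alpha=0.05, power=0.80)
    n_b = evaluation.required_n_binomial(p1=0.7, p0=0.5, alpha=0.05,
                                         power=0.80)
    out = {"required_n_ttest_d05": n_t, "required_n_binomial_07_vs_05": n_b}
    dd = _outdir(cfg)
    (dd / "power.json").write_text(json.dumps(out, indent=1))
    log("power", **out)
    return out
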