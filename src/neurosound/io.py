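"""Artifact serialization.

Stimuli as 16-bit PCM WAV plus a CSV manifest; voxel data, datasets,
decoders, codebooks and translators as HDF5; run configs and provenance as
JSON/YAML sidecars. Every writer embeds the config hash and seed it was
produced under so a run is reproducible from its artifacts alone.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from . import dsp
from .decoding import FeatureDecoder, NormStats
from .generator import Codebook, Translator
from .sampling import DataSample, Dataset
from .synth import SyntheticStimulus, VoxelTimeSeries


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True,
                                     default=str).encode()).hexdigest()[:12]


# ------------------------------------------------------------------ waveforms
def write_wav(path, wave: np.ndarray, rate: int = dsp.SAMPLE_RATE):
    data = np.clip(np.asarray(wave), -1.0, 1.0)
    wavfile.write(str(path), rate, (data * 32767).astype(np.int16))


def read_wav(path) -> tuple[np.ndarray, int]:
    rate, data = wavfile.read(str(path))
    return data.astype(np.float64) / 32767.0, rate


def write_stimuli(dirpath, stimuli: list[SyntheticStimulus], seed: int | None = None):
    """WAV files plus a manifest CSV (id, category, duration, seed)."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in stimuli:
        write_wav(d / f"{s.id}.wav", s.wave, s.rate)
        rows.append((s.id, s.category, s.duration, seed))
    pd.DataFrame(rows, columns=["id", "category", "duration", "seed"]
                 ).to_csv(d / "manifest.csv", index=False)


# ----------------------------------------------------------------- voxel data
def write_voxel_series(path, series: list[VoxelTimeSeries],
                       roi_labels: np.ndarray | None = None,
                       meta: dict | None = None):
    with h5py.File(path, "w") as f:
        g = f.create_group("volumes")
        for i, v in enumerate(series):
            d = g.create_dataset(str(i), data=v.volumes)
            d.attrs["stimulus_id"] = v.stimulus_id
            d.attrs["repetition"] = v.repetition
            d.attrs["condition"] = v.condition
            d.attrs["times"] = v.times
        if roi_labels is not None:
            f.create_dataset("roi_labels",
                             data=np.asarray(roi_labels, dtype="S16"))
        f.create_group("meta").attrs.update(meta or {})


def read_voxel_series(path) -> tuple[list[VoxelTimeSeries], np.ndarray | None]:
    out = []
    with h5py.File(path, "r") as f:
        g = f["volumes"]
        for key in sorted(g, key=int):
            d = g[key]
            out.append(VoxelTimeSeries(
                stimulus_id=d.attrs["stimulus_id"],
                repetition=int(d.attrs["repetition"]),
                volumes=d[()], condition=d.attrs["condition"],
                times=np.asarray(d.attrs["times"])))
        rois = (f["roi_labels"][()].astype(str)
                if "roi_labels" in f else None)
    return out, rois


# ------------------------------------------------------------------- dataset
def write_dataset(path, ds: Dataset):
    with h5py.File(path, "w") as f:
        f.create_dataset("samples/voxels", data=ds.voxel_matrix())
        if all(s.target is not None for s in ds.samples):
            f.create_dataset("samples/targets", data=ds.target_matrix())
        meta = f.create_group("samples/meta")
        meta.create_dataset("stimulus_id", data=np.array(
            [s.stimulus_id for s in ds.samples], dtype="S64"))
        meta.create_dataset("window_index", data=np.array(
            [s.window_index for s in ds.samples]))
        meta.create_dataset("n_trials_averaged", data=np.array(
            [s.n_trials_averaged for s in ds.samples]))
        meta.create_dataset("category", data=np.array(
            [s.category or "" for s in ds.samples], dtype="S32"))
        f.attrs["design"] = json.dumps(ds.design)


def read_dataset(path) -> Dataset:
    with h5py.File(path, "r") as f:
        X = f["samples/voxels"][()]
        Y = f["samples/targets"][()] if "samples/targets" in f else None
        meta = f["samples/meta"]
        sids = meta["stimulus_id"][()].astype(str)
        wins = meta["window_index"][()]
        navg = meta["n_trials_averaged"][()]
        cats = meta["category"][()].astype(str)
        design = json.loads(f.attrs["design"])
    samples = [DataSample(stimulus_id=sids[i], window_index=int(wins[i]),
                          voxel_vector=X[i],
                          target=None if Y is None else Y[i],
                          condition=design.get("condition", "train"),
                          n_trials_averaged=int(navg[i]),
                          category=cats[i] or None)
               for i in range(len(sids))]
    return Dataset(samples=samples, design=design)


# -------------------------------------------------------------------- models
def write_decoder(path, dec: FeatureDecoder, extra_meta: dict | None = None):
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=dec.weights)
        f.create_dataset("bias", data=dec.bias)
        f.create_dataset("voxel_indices", data=dec.voxel_indices)
        for name, st in (("x", dec.x_stats), ("y", dec.y_stats)):
            g = f.create_group(f"norm_stats/{name}")
            g.create_dataset("mean", data=st.mean)
            g.create_dataset("sd", data=st.sd)
            g.attrs["source"] = st.source
        f.attrs.update({"lambda": dec.lam, "layer": dec.layer,
                        "trial_scale_rule": dec.trial_scale_rule,
                        "excluded_category": dec.excluded_category or "",
                        **(extra_meta or {})})


def read_decoder(path) -> FeatureDecoder:
    with h5py.File(path, "r") as f:
        stats = {}
        for name in ("x", "y"):
            g = f[f"norm_stats/{name}"]
            stats[name] = NormStats(mean=g["mean"][()], sd=g["sd"][()],
                                    source=g.attrs["source"])
        return FeatureDecoder(
            voxel_indices=f["voxel_indices"][()], weights=f["weights"][()],
            bias=f["bias"][()], lam=float(f.attrs["lambda"]),
            x_stats=stats["x"], y_stats=stats["y"],
            layer=f.attrs["layer"],
            trial_scale_rule=f.attrs["trial_scale_rule"],
            excluded_category=f.attrs["excluded_category"] or None)


def write_codebook(path, cb: Codebook):
    with h5py.File(path, "w") as f:
        f.create_dataset("codes", data=cb.codes)
        f.attrs.update({k: v for k, v in cb.fit_meta.items()})


def read_codebook(path) -> Codebook:
    with h5py.File(path, "r") as f:
        return Codebook(codes=f["codes"][()], fit_meta=dict(f.attrs))


def write_translator(path, tr: Translator):
    with h5py.File(path, "w") as f:
        f.attrs.update({"n_units": tr.n_units, "context": tr.context,
                        "lambda": tr.lam, "layer": tr.layer, "seed": tr.seed})
        for pos in range(tr.n_positions):
            g = f.create_group(f"pos/{pos}")
            g.create_dataset("classes", data=tr.classes[pos])
            if tr.weights[pos] is not None:
                g.create_dataset("weights",
                                 data=tr.weights[pos].astype(np.float32))
        if tr.loss_trace is not None:
            f.create_dataset("loss_trace", data=tr.loss_trace)
        if tr.feat_mean is not None:
            f.create_dataset("feat_mean", data=tr.feat_mean)
            f.create_dataset("feat_sd", data=tr.feat_sd)


def read_translator(path) -> Translator:
    with h5py.File(path, "r") as f:
        tr = Translator(n_units=int(f.attrs["n_units"]),
                        context=int(f.attrs["context"]),
                        lam=float(f.attrs["lambda"]),
                        layer=f.attrs["layer"], seed=int(f.attrs["seed"]))
        for pos in range(tr.n_positions):
            g = f[f"pos/{pos}"]
            tr.classes.append(g["classes"][()])
            tr.weights.append(g["weights"][()].astype(np.float64)
                              if "weights" in g else None)
        if "loss_trace" in f:
            tr.loss_trace = f["loss_trace"][()]
        if "feat_mean" in f:
            tr.feat_mean = f["feat_mean"][()]
            tr.feat_sd = f["feat_sd"][()]
    return tr
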