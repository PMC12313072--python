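"""The audio-generator stack.

A 256-entry patch codebook over 16 x 16 spectrogram tiles (k-means
quantization of the 80 x 336 log-mel plane into a 5 x 21 index grid), an
autoregressive feature-to-code translator (per-raster-position 256-way
softmax classifiers over the conditioning features and previously generated
indices), Griffin-Lim mel inversion back to a waveform, and the three
reconstruction pipelines: the full feature-decoder route, the direct
brain-to-codebook route, and the pixel-optimization baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from . import dsp
from .features import (MEL_FLOOR, N_FRAMES, N_MELS, MelSpectrogram,
                       melspectrogram, _MEL_FB)
from .decoding import FeatureDecoder, fit_decoder, trial_scale
from .nnet import HierarchyNet
from .sampling import DataSample

N_CODES = 256
PATCH = 16
GRID_ROWS = N_MELS // PATCH      # 5
GRID_COLS = N_FRAMES // PATCH    # 21
PATCH_DIM = PATCH * PATCH


def spec_to_patches(values: np.ndarray) -> np.ndarray:
    """(80, 336) -> (5, 21, 256) row-major 16 x 16 patches."""
    v = values.reshape(GRID_ROWS, PATCH, GRID_COLS, PATCH)
    return v.transpose(0, 2, 1, 3).reshape(GRID_ROWS, GRID_COLS, PATCH_DIM)


def patches_to_spec(patches: np.ndarray) -> np.ndarray:
    """(5, 21, 256) -> (80, 336)."""
    v = patches.reshape(GRID_ROWS, GRID_COLS, PATCH, PATCH)
    return v.transpose(0, 2, 1, 3).reshape(N_MELS, N_FRAMES)


@dataclass
class Codebook:
    codes: np.ndarray                       # (256, 256) entries x patch dim
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.float64)
        if self.codes.shape != (N_CODES, PATCH_DIM):
            raise ValueError(f"codebook must be ({N_CODES}, {PATCH_DIM})")
        if len(np.unique(self.codes, axis=0)) != N_CODES:
            raise ValueError("codebook entries must be distinct")


@dataclass
class CodeGrid:
    indices: np.ndarray                     # (5, 21) ints in [0, 256)

    def __post_init__(self):
        self.indices = np.asarray(self.indices)
        if self.indices.shape != (GRID_ROWS, GRID_COLS):
            raise ValueError(f"code grid must be {GRID_ROWS} x {GRID_COLS}")
        if self.indices.min() < 0 or self.indices.max() >= N_CODES:
            raise ValueError("code index out of range")

    def raster(self) -> np.ndarray:
        """Indices in raster order: spectral-major within each temporal step."""
        return self.indices.T.reshape(-1)

    @classmethod
    def from_raster(cls, flat: np.ndarray) -> "CodeGrid":
        return cls(indices=np.asarray(flat).reshape(GRID_COLS, GRID_ROWS).T)


@dataclass
class ReconstructedAudio:
    """A reconstruction; ``wave`` is None when audio rendering was skipped."""

    wave: np.ndarray | None
    spec: MelSpectrogram
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.wave is not None:
            if not np.all(np.isfinite(self.wave)):
                raise ValueError("reconstructed waveform must be finite")
            if np.max(np.abs(self.wave)) > 1.0 + 1e-9:
                raise ValueError("reconstructed waveform must have peak <= 1")


# -------------------------------------------------------------------- codec
def fit_codebook(specs: list[MelSpectrogram], n_codes: int = N_CODES,
                 seed: int = 0) -> Codebook:
    """k-means over all 16 x 16 patches of the corpus, k = 256.

    Duplicate centers (possible in degenerate corpora) are re-seeded from the
    patches farthest from their assigned centers, mirroring empty-cluster
    relocation.
    """
    patches = np.concatenate([spec_to_patches(s.values).reshape(-1, PATCH_DIM)
                              for s in specs])
    if len(np.unique(patches, axis=0)) < n_codes:
        raise ValueError(
            f"corpus has fewer than {n_codes} distinct patches; supply more "
            "or more varied spectrograms")
    km = KMeans(n_clusters=n_codes, n_init=1, random_state=seed)
    km.fit(patches)
    codes = km.cluster_centers_.copy()
    # enforce distinct entries
    _, first = np.unique(codes, axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(n_codes), first)
    if len(dup):
        d = cdist(patches, codes, "sqeuclidean").min(axis=1)
        far = np.argsort(-d)
        for j, ci in enumerate(dup):
            codes[ci] = patches[far[j]]
    return Codebook(codes=codes, fit_meta={"seed": seed,
                                           "n_patches": len(patches),
                                           "inertia": float(km.inertia_)})


def quantize_patches(patches: np.ndarray, cb: Codebook) -> np.ndarray:
    """Nearest code (Euclidean, ties to the lowest index) per patch row."""
    d = cdist(np.atleast_2d(patches), cb.codes, "sqeuclidean")
    return np.argmin(d, axis=1)


def encode(spec: MelSpectrogram, cb: Codebook) -> CodeGrid:
    """Tile an 80 x 336 spectrogram and map each patch to its nearest code."""
    if spec.values.shape != (N_MELS, N_FRAMES):
        raise ValueError(f"expected (80, 336) input, got {spec.values.shape}")
    patches = spec_to_patches(spec.values).reshape(-1, PATCH_DIM)
    idx = quantize_patches(patches, cb)
    return CodeGrid(indices=idx.reshape(GRID_ROWS, GRID_COLS))


def decode(grid: CodeGrid, cb: Codebook) -> MelSpectrogram:
    """Paste code patches back into the 80 x 336 canvas."""
    patches = cb.codes[grid.indices.reshape(-1)]
    return MelSpectrogram(
        values=patches_to_spec(patches.reshape(GRID_ROWS, GRID_COLS, PATCH_DIM)))


# --------------------------------------------------------------- translator
@dataclass
class Translator:
    """Per-raster-position softmax classifiers with autoregressive context.

    Position (s, t) in raster order (spectral-major within each temporal
    step) sees the conditioning feature columns t and t-1 plus the one-hot
    codes of the previous ``context`` indices; generation therefore depends
    only on features and indices earlier in raster order.
    """

    n_units: int
    context: int = 5
    lam: float = 1e-5
    weights: list = field(default_factory=list, repr=False)   # (d+1, C) per position
    classes: list = field(default_factory=list, repr=False)
    loss_trace: np.ndarray | None = None
    layer: str = "L5"
    seed: int = 0
    #: conditioning-feature standardization fitted on the training corpus
    feat_mean: np.ndarray | None = None
    feat_sd: np.ndarray | None = None

    @property
    def n_positions(self) -> int:
        return GRID_ROWS * GRID_COLS

    def _norm(self, features: np.ndarray) -> np.ndarray:
        if self.feat_mean is None:
            return features
        return (features - self.feat_mean[:, None]) / self.feat_sd[:, None]

    def _context_matrix(self, features: np.ndarray, raster: np.ndarray | None,
                        pos: int, normalized: bool = False) -> np.ndarray:
        """Design row for one raster position.

        features: (n_units, 21) conditioning; raster: previously generated
        raster-order indices (length >= pos) or the full training raster.
        """
        if not normalized:
            features = self._norm(features)
        t = pos // GRID_ROWS
        cols = [features[:, t]]
        cols.append(features[:, t - 1] if t > 0 else np.zeros(self.n_units))
        ctx = np.zeros(self.context * N_CODES)
        for j in range(1, self.context + 1):
            p = pos - j
            if p >= 0:
                ctx[(j - 1) * N_CODES + int(raster[p])] = 1.0
        return np.concatenate(cols + [ctx, [1.0]])   # trailing intercept


def _softmax_ce(K, A, y_onehot, lam):
    """Objective/gradient of ridge softmax CE in the representer form."""
    logits = K @ A
    logits -= logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    p = e / e.sum(axis=1, keepdims=True)
    n = K.shape[0]
    ll = -np.sum(y_onehot * np.log(np.maximum(p, 1e-12))) / n
    reg = 0.5 * lam * np.sum(A * (K @ A))
    g = K @ (p - y_onehot) / n + lam * (K @ A)
    return ll + reg, g


def fit_translator(features_list: list[np.ndarray], grids: list[CodeGrid],
                   seed: int = 0, context: int = 5, lam: float = 1e-5,
                   maxiter: int = 200, layer: str = "L5",
                   min_corpus: int = 50) -> Translator:
    """Fit the per-position classifiers by minimizing cross-entropy.

    ``features_list`` holds (units x 21) conditioning arrays paired with the
    target code grids. Each position's multinomial logistic model is solved
    in the span of its training rows (the exact minimizer of the
    L2-regularized objective) with L-BFGS; the summed training loss per
    outer iteration is recorded in ``loss_trace``.
    """
    if len(features_list) != len(grids):
        raise ValueError("features and grids must pair one-to-one")
    if len(features_list) < min_corpus:
        raise ValueError(f"translator corpus of {len(features_list)} is "
                         f"below the minimum of {min_corpus} samples")
    n_units = features_list[0].shape[0]
    tr = Translator(n_units=n_units, context=context, lam=lam, layer=layer,
                    seed=seed)
    stacked = np.concatenate(features_list, axis=1)
    tr.feat_mean = stacked.mean(axis=1)
    sd = stacked.std(axis=1)
    tr.feat_sd = np.where(sd < 1e-12, 1.0, sd)
    normed = [tr._norm(f) for f in features_list]
    rasters = [g.raster() for g in grids]
    n = len(features_list)
    traces = []
    for pos in range(tr.n_positions):
        X = np.stack([tr._context_matrix(f, r, pos, normalized=True)
                      for f, r in zip(normed, rasters)])
        y = np.array([r[pos] for r in rasters])
        cls = np.unique(y)
        tr.classes.append(cls)
        if len(cls) == 1:   # degenerate position: constant predictor
            tr.weights.append(None)
            traces.append(np.zeros(1))
            continue
        Y = (y[:, None] == cls[None, :]).astype(float)
        K = X @ X.T
        A0 = np.zeros((n, len(cls)))
        trace = []

        def fun(a_flat):
            val, g = _softmax_ce(K, a_flat.reshape(n, len(cls)), Y, lam)
            return val, g.ravel()

        res = minimize(fun, A0.ravel(), jac=True, method="L-BFGS-B",
                       callback=lambda a: trace.append(
                           _softmax_ce(K, a.reshape(n, len(cls)), Y, lam)[0]),
                       options={"maxiter": maxiter, "ftol": 1e-10})
        A = res.x.reshape(n, len(cls))
        tr.weights.append(X.T @ A)      # explicit primal weights (d+1, C)
        traces.append(np.array(trace) if trace else np.array([res.fun]))
    m = max(len(t) for t in traces)
    padded = np.stack([np.pad(t, (0, m - len(t)), mode="edge") for t in traces])
    tr.loss_trace = padded.sum(axis=0)
    return tr


def generate_codes(tr: Translator, features: np.ndarray,
                   mode: str = "argmax", seed: int = 0) -> CodeGrid:
    """Raster-order autoregressive generation of a 5 x 21 code grid."""
    if features.shape != (tr.n_units, GRID_COLS):
        raise ValueError(f"conditioning features must be "
                         f"({tr.n_units}, {GRID_COLS}), got {features.shape}")
    if mode not in ("argmax", "sample"):
        raise ValueError("mode must be 'argmax' or 'sample'")
    rng = np.random.default_rng(seed)
    raster = np.zeros(tr.n_positions, dtype=int)
    for pos in range(tr.n_positions):
        cls = tr.classes[pos]
        if tr.weights[pos] is None:
            raster[pos] = cls[0]
            continue
        x = tr._context_matrix(features, raster, pos)
        logits = x @ tr.weights[pos]
        if mode == "argmax":
            raster[pos] = cls[int(np.argmax(logits))]
        else:
            logits = logits - logits.max()
            p = np.exp(logits)
            p /= p.sum()
            raster[pos] = cls[rng.choice(len(cls), p=p)]
    return CodeGrid.from_raster(raster)


# ------------------------------------------------------------------- vocoder
def invert_spectrogram(spec: MelSpectrogram, gl_iters: int = 60,
                       seed: int = 0) -> np.ndarray:
    """Log-mel (80 x 336) back to a 4-s waveform.

    Undoes the log (subtracting the mel floor), inverts the mel projection by
    non-negative least squares, recovers phase with Griffin-Lim, re-centers
    the 336-frame segment inside the original 345-frame span, and scales down
    if the peak would exceed 1.
    """
    v = spec.values
    if v.shape != (N_MELS, N_FRAMES):
        raise ValueError(f"expected (80, 336) log-mel input, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite spectrogram")
    mel_power = np.maximum(np.exp(v) - MEL_FLOOR, 0.0)
    lin_power = dsp.nnls_columns(_MEL_FB, mel_power)
    mag = np.sqrt(lin_power)
    n_body = N_FRAMES * dsp.HOP
    wave = dsp.griffin_lim(mag, n_iter=gl_iters, length=n_body, seed=seed)
    # undo the 345 -> 336 center crop: 4 cropped frames on the left
    pad_left = 4 * dsp.HOP
    total = 4 * dsp.SAMPLE_RATE
    out = np.zeros(total)
    out[pad_left:pad_left + n_body] = wave
    peak = np.max(np.abs(out))
    if peak > 1.0:
        out /= peak
    return out


# ----------------------------------------------------------------- pipelines
def reconstruct_full(dec: FeatureDecoder, cb: Codebook, tr: Translator,
                     sample: DataSample, mode: str = "argmax",
                     seed: int = 0, features: np.ndarray | None = None,
                     render_audio: bool = True) -> ReconstructedAudio:
    """fMRI sample -> decoded features -> codes -> spectrogram -> waveform.

    Passing ``features`` (units x 21) bypasses the decoder: the recovery
    check that bounds the generator's best case with true stimulus features.
    ``render_audio=False`` skips the Griffin-Lim stage (wave = None).
    """
    if features is None:
        if dec.layer != tr.layer:
            raise ValueError(f"decoder layer {dec.layer!r} does not match "
                             f"translator layer {tr.layer!r}")
        # condition the translator on distribution-matched decoded features:
        # the trial-averaging factor restores the attenuated deviations
        # around the training mean, aligning the decoded distribution with
        # the true-feature distribution the translator was trained on
        flat = dec.predict_matched(sample.voxel_vector,
                                   n_trials=sample.n_trials_averaged)
        features = flat.reshape(tr.n_units, GRID_COLS)
        pipeline = "full"
    else:
        pipeline = "recovery_check"
    grid = generate_codes(tr, features, mode=mode, seed=seed)
    spec = decode(grid, cb)
    wave = invert_spectrogram(spec, seed=seed) if render_audio else None
    return ReconstructedAudio(wave=wave, spec=spec, provenance={
        "pipeline": pipeline, "layer": tr.layer,
        "stimulus_id": sample.stimulus_id, "window": sample.window_index,
        "seed": seed, "mode": mode})


def fit_codebook_decoder(X: np.ndarray, specs: list[MelSpectrogram],
                         k: int | None = None, lam: float = 100.0,
                         **kwargs) -> FeatureDecoder:
    """Ridge decoder from voxels to the continuous 5 x 21 patch-space
    representation (the pre-quantization latents of the codec)."""
    Y = np.stack([spec_to_patches(s.values).reshape(-1) for s in specs])
    return fit_decoder(X, Y, k=k, lam=lam, layer="codebook", **kwargs)


def reconstruct_brain_to_codebook(dec: FeatureDecoder, cb: Codebook,
                                  sample: DataSample, seed: int = 0,
                                  render_audio: bool = True,
                                  ) -> ReconstructedAudio:
    """Decode continuous patch vectors from voxels, quantize each to its
    nearest code, then run the codebook decoder and the vocoder."""
    flat = dec.predict(sample.voxel_vector, n_trials=sample.n_trials_averaged)
    patches = flat.reshape(GRID_ROWS * GRID_COLS, PATCH_DIM)
    idx = quantize_patches(patches, cb)
    grid = CodeGrid(indices=idx.reshape(GRID_ROWS, GRID_COLS))
    spec = decode(grid, cb)
    wave = invert_spectrogram(spec, seed=seed) if render_audio else None
    return ReconstructedAudio(wave=wave, spec=spec, provenance={
        "pipeline": "brain_to_codebook",
        "stimulus_id": sample.stimulus_id, "window": sample.window_index,
        "seed": seed})


# ------------------------------------------------------- pixel optimization
def pixel_optimize(decoded_features: dict[str, np.ndarray],
                   net: HierarchyNet, iters: int = 600, lr: float = 0.05,
                   seed: int = 0, relu_leak: float = 0.1,
                   ) -> tuple[MelSpectrogram, np.ndarray]:
    """Optimize spectrogram pixels to match decoded features at every layer.

    Starts from seeded Gaussian noise and minimizes the summed per-layer
    normalized squared feature mismatch by Adam, with gradients backpropagated
    through the hierarchy (a leaky surrogate slope on inactive ReLUs keeps
    descent directions available; the loss itself is exact). Returns
    (spectrogram, loss trace); non-convergence is reported through the
    trace, never raised.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(np.log(MEL_FLOOR) / 2, 1.0, (N_MELS, N_FRAMES))
    targets = {k: np.atleast_2d(v) for k, v in decoded_features.items()}
    m = np.zeros_like(x)
    v = np.zeros_like(x)
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    trace = np.empty(iters + 1)
    # step size anneals in thirds for fine convergence near the optimum
    lrs = np.repeat([lr, lr / 5, lr / 25], int(np.ceil((iters + 1) / 3)))
    for it in range(iters + 1):
        acts, cache = net.forward(x, keep_cache=True)
        loss = 0.0
        grads = {}
        for name, tgt in targets.items():
            diff = acts[name] - tgt
            scale = 1.0 / tgt.size
            loss += 0.5 * scale * np.sum(diff ** 2)
            grads[name] = scale * diff
        trace[it] = loss
        if it == iters:
            break
        g = net.backward_input(cache, grads, relu_leak=relu_leak)
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g * g
        mhat = m / (1 - beta1 ** (it + 1))
        vhat = v / (1 - beta2 ** (it + 1))
        x = x - lrs[it] * mhat / (np.sqrt(vhat) + eps)
    return MelSpectrogram(values=x), trace
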