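"""A small 1-D convolutional network over log-mel spectrograms.

This is the package's stand-in for a large pretrained sound-recognition CNN:
a six-level hierarchy whose temporal geometry halves at every convolutional
level (336 -> 168 -> 84 -> 42 -> 21) and ends in a fully connected category
readout with no temporal axis. Mel bands enter as input channels, so each
level's feature map has shape (channels, time) and flattens to the
``units x temporal`` layout used as decoding targets and generator
conditioning.

Forward, input-gradient and weight-gradient passes are written directly in
numpy (im2col convolutions); the input-gradient pass drives the
pixel-optimization reconstruction baseline, and the weight-gradient pass
lets the hierarchy be fitted to synthetic category classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LAYER_NAMES = ("L1", "L2", "L3", "L4", "L5", "FC")
#: temporal length of each layer's feature map for an 80 x 336 input
LAYER_TEMPORAL = {"L1": 336, "L2": 168, "L3": 84, "L4": 42, "L5": 21, "FC": 1}
DEFAULT_CHANNELS = (16, 32, 64, 64, 64)
KERNEL = 3


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(C, T) -> (C*k, T) with zero padding, stride 1."""
    c, t = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p)))
    cols = np.empty((c * k, t))
    for j in range(k):
        cols[j * c:(j + 1) * c] = xp[:, j:j + t]
    return cols


def _col2im(gcols: np.ndarray, c: int, t: int, k: int) -> np.ndarray:
    """Adjoint of _im2col."""
    p = k // 2
    gxp = np.zeros((c, t + 2 * p))
    for j in range(k):
        gxp[:, j:j + t] += gcols[j * c:(j + 1) * c]
    return gxp[:, p:p + t]


@dataclass
class HierarchyNet:
    """Six-level conv hierarchy with ReLU and stride-2 mean pooling."""

    n_mels: int = 80
    n_categories: int = 4
    channels: tuple = DEFAULT_CHANNELS
    seed: int = 0
    trained: bool = False
    conv_w: list = field(default_factory=list, repr=False)
    conv_b: list = field(default_factory=list, repr=False)
    fc_w: np.ndarray | None = field(default=None, repr=False)
    fc_b: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        if not self.conv_w:
            rng = np.random.default_rng(self.seed)
            c_in = self.n_mels
            for c_out in self.channels:
                std = np.sqrt(2.0 / (c_in * KERNEL))
                self.conv_w.append(rng.normal(0.0, std, (c_out, c_in * KERNEL)))
                self.conv_b.append(np.zeros(c_out))
                c_in = c_out
            self.fc_w = rng.normal(0.0, np.sqrt(1.0 / c_in),
                                   (self.n_categories, c_in))
            self.fc_b = np.zeros(self.n_categories)

    # ---------------------------------------------------------------- forward
    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Return {layer: (channels, T)} activations for an (80, 336) input."""
        acts: dict[str, np.ndarray] = {}
        cache = []
        h = np.asarray(x, dtype=np.float64)
        for i, name in enumerate(LAYER_NAMES[:-1]):
            if i > 0:  # stride-2 mean pooling halves the temporal axis
                h = 0.5 * (h[:, 0::2] + h[:, 1::2])
            cols = _im2col(h, KERNEL)
            pre = self.conv_w[i] @ cols + self.conv_b[i][:, None]
            relu_mask = pre > 0
            h_out = pre * relu_mask
            if keep_cache:
                cache.append((h.shape, cols, relu_mask))
            h = h_out
            acts[name] = h
        pooled = h.mean(axis=1)  # global average over the 21 L5 frames
        logits = self.fc_w @ pooled + self.fc_b
        acts["FC"] = logits[:, None]
        if keep_cache:
            cache.append((h.shape, pooled))
            return acts, cache
        return acts

    # ------------------------------------------------------------- input grad
    def backward_input(self, cache, grads: dict[str, np.ndarray],
                       relu_leak: float = 0.0) -> np.ndarray:
        """Gradient w.r.t. the input spectrogram of sum_l <grads[l], act_l>.

        ``relu_leak`` > 0 substitutes a leaky surrogate slope for inactive
        ReLU units — a descent direction that lets input optimization escape
        dead-unit plateaus; the forward pass (and any loss measured on it)
        keeps the exact ReLU.
        """
        g = np.zeros_like(cache[-1][1])  # grad wrt pooled L5 vector
        if "FC" in grads:
            g = self.fc_w.T @ grads["FC"][:, 0]
        h_shape_l5 = cache[-1][0]
        gh = np.tile((g / h_shape_l5[1])[:, None], (1, h_shape_l5[1]))
        for i in range(len(self.channels) - 1, -1, -1):
            name = LAYER_NAMES[i]
            if name in grads:
                gh = gh + grads[name]
            h_shape, cols, relu_mask = cache[i]
            gpre = gh * np.where(relu_mask, 1.0, relu_leak)
            gcols = self.conv_w[i].T @ gpre
            gin = _col2im(gcols, h_shape[0], h_shape[1], KERNEL)
            if i > 0:  # adjoint of mean pooling: spread half the grad to each
                up = np.zeros((gin.shape[0], gin.shape[1] * 2))
                up[:, 0::2] = 0.5 * gin
                up[:, 1::2] = 0.5 * gin
                gin = up
            gh = gin
        return gh

    # ------------------------------------------------------------ weight grad
    def _backward_weights(self, cache, glogits: np.ndarray):
        """Gradients of a scalar loss w.r.t. all weights, given dL/dlogits."""
        gw_conv = [np.zeros_like(w) for w in self.conv_w]
        gb_conv = [np.zeros_like(b) for b in self.conv_b]
        _, pooled = cache[-1]
        gw_fc = np.outer(glogits, pooled)
        gb_fc = glogits.copy()
        g_pooled = self.fc_w.T @ glogits
        t_l5 = cache[-1][0][1]
        gh = np.tile((g_pooled / t_l5)[:, None], (1, t_l5))
        for i in range(len(self.channels) - 1, -1, -1):
            h_shape, cols, relu_mask = cache[i]
            gpre = gh * relu_mask
            gw_conv[i] = gpre @ cols.T
            gb_conv[i] = gpre.sum(axis=1)
            if i > 0:
                gcols = self.conv_w[i].T @ gpre
                gin = _col2im(gcols, h_shape[0], h_shape[1], KERNEL)
                up = np.zeros((gin.shape[0], gin.shape[1] * 2))
                up[:, 0::2] = 0.5 * gin
                up[:, 1::2] = 0.5 * gin
                gh = up
        return gw_conv, gb_conv, gw_fc, gb_fc

    def fit_classifier(self, specs: list[np.ndarray], labels: np.ndarray,
                       epochs: int = 20, lr: float = 1e-3,
                       seed: int = 0) -> list[float]:
        """Fit all weights on category classification by Adam on softmax CE.

        ``specs`` are (80, 336) log-mel arrays, ``labels`` integer categories.
        Returns the per-epoch mean training loss. Marks the net as trained.
        """
        rng = np.random.default_rng(seed)
        params = self.conv_w + self.conv_b + [self.fc_w, self.fc_b]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        losses = []
        labels = np.asarray(labels)
        for ep in range(epochs):
            order = rng.permutation(len(specs))
            total = 0.0
            for idx in order:
                acts, cache = self.forward(specs[idx], keep_cache=True)
                logits = acts["FC"][:, 0]
                z = logits - logits.max()
                p = np.exp(z) / np.exp(z).sum()
                total += -np.log(max(p[labels[idx]], 1e-12))
                glog = p.copy()
                glog[labels[idx]] -= 1.0
                gw_conv, gb_conv, gw_fc, gb_fc = self._backward_weights(cache, glog)
                grads = gw_conv + gb_conv + [gw_fc, gb_fc]
                step += 1
                for j, (par, g) in enumerate(zip(params, grads)):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - beta1 ** step)
                    vhat = v[j] / (1 - beta2 ** step)
                    par -= lr * mhat / (np.sqrt(vhat) + eps)
            losses.append(total / len(specs))
        self.trained = True
        return losses
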