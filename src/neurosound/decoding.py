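"""Voxel-to-feature linear decoders.

Correlation-based voxel selection (500 voxels for the whole auditory cortex,
200 per individual ROI in the full-scale design), z-scoring of voxels and
targets by training statistics, per-unit ridge regression with the closed
form (X'X + lambda I)^-1 X'Y at lambda = 100, denormalization, and the
post-hoc rescaling of decoded values by the number of trials averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sampling import Dataset

DEFAULT_LAMBDA = 100.0


@dataclass
class NormStats:
    mean: np.ndarray
    sd: np.ndarray
    source: str = "voxels"
    zero_variance: np.ndarray | None = None  # flagged dims, sd replaced by 1

    @classmethod
    def fit(cls, X: np.ndarray, source: str) -> "NormStats":
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        zero = sd < 1e-12
        sd = np.where(zero, 1.0, sd)
        return cls(mean=mean, sd=sd, source=source, zero_variance=zero)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def undo(self, Z: np.ndarray) -> np.ndarray:
        return Z * self.sd + self.mean


def correlation_matrix(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between every column of X and every column of Y.

    Constant columns yield r = 0 rather than NaN.
    """
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0, ddof=0)
    sy = Yc.std(axis=0, ddof=0)
    R = (Xc / np.where(sx < 1e-12, np.inf, sx)).T @ \
        (Yc / np.where(sy < 1e-12, np.inf, sy)) / n
    return R


def select_voxels(X: np.ndarray, Y: np.ndarray, k: int,
                  score: str = "max") -> np.ndarray:
    """Top-k voxels by |Pearson r| with the target units on training data.

    ``score`` aggregates over units by ``max`` (default) or ``mean`` of |r|;
    ties break toward the lower voxel index.
    """
    if X.shape[0] < 3:
        raise ValueError("voxel selection needs at least 3 samples")
    if k > X.shape[1]:
        raise ValueError(f"cannot select {k} voxels from {X.shape[1]}")
    R = np.abs(correlation_matrix(X, Y))
    s = R.max(axis=1) if score == "max" else R.mean(axis=1)
    order = np.argsort(-s, kind="stable")  # stable: lower index wins ties
    return np.sort(order[:k])


@dataclass
class FeatureDecoder:
    voxel_indices: np.ndarray
    weights: np.ndarray              # (selected voxels, units) on z-scored data
    bias: np.ndarray
    lam: float
    x_stats: NormStats
    y_stats: NormStats
    layer: str = "L5"
    trial_scale_rule: str = "n"      # "n" (literal) or "sqrt_n"
    excluded_category: str | None = None

    def predict(self, x: np.ndarray, n_trials: int = 1) -> np.ndarray:
        """Decode one voxel vector (or a samples x voxels matrix).

        Normalizes with the training voxel statistics, applies the ridge
        weights, denormalizes with the training target statistics, and
        finally rescales the decoded values by the trial-averaging rule
        (a factor of n by default) — a global scaling, so correlation-based
        evaluations are provably unaffected.
        """
        x = np.asarray(x, dtype=np.float64)
        one = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] == len(self.x_stats.mean):
            pass  # already restricted to the selected voxels
        elif X.shape[1] > np.max(self.voxel_indices):
            X = X[:, self.voxel_indices]
        else:
            raise ValueError(
                f"input has {X.shape[1]} voxels; decoder needs the "
                f"{len(self.voxel_indices)} selected voxels (max index "
                f"{np.max(self.voxel_indices)})")
        Z = self.x_stats.apply(X)
        Yn = Z @ self.weights + self.bias
        Y = self.y_stats.undo(Yn)
        Y = Y * trial_scale(n_trials, self.trial_scale_rule)
        return Y[0] if one else Y

    def predict_matched(self, x: np.ndarray, n_trials: int = 1) -> np.ndarray:
        """Decode with the trial factor applied as distribution matching.

        Restores the decoded deviations about the training target mean by
        the trial-averaging factor (``mean + n * (yhat - mean)``), aligning
        the decoded-feature distribution with the true-feature distribution
        — the calibration used wherever decoded features stand in for true
        ones (generator conditioning, two-candidate attention scoring).
        Identity at n = 1.
        """
        y1 = self.predict(x, n_trials=1)
        scale = trial_scale(n_trials, self.trial_scale_rule)
        return self.y_stats.mean + scale * (y1 - self.y_stats.mean)


def trial_scale(n_trials: int, rule: str = "n") -> float:
    """Post-hoc scale applied to decoded values (identity at n=1)."""
    if rule == "n":
        return float(n_trials)
    if rule == "sqrt_n":
        return float(np.sqrt(n_trials))
    raise ValueError(f"unknown trial scale rule {rule!r}")


def fit_decoder(X: np.ndarray, Y: np.ndarray, k: int | None = None,
                lam: float = DEFAULT_LAMBDA, layer: str = "L5",
                voxel_score: str = "max",
                trial_scale_rule: str = "n") -> FeatureDecoder:
    """Fit the ridge decoder on training samples.

    X is samples x voxels, Y samples x feature units. ``k`` selects voxels by
    correlation first (None keeps all). Both sides are z-scored with training
    statistics before the per-unit closed-form ridge solve.
    """
    X = np.asarray(X, dtype=np.float64)
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("X and Y sample counts differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("training data must be finite")
    if k is not None:
        idx = select_voxels(X, Y, k, score=voxel_score)
    else:
        idx = np.arange(X.shape[1])
    Xs = X[:, idx]
    x_stats = NormStats.fit(Xs, "voxels")
    y_stats = NormStats.fit(Y, "features")
    Z = x_stats.apply(Xs)
    T = y_stats.apply(Y)
    G = Z.T @ Z + lam * np.eye(Z.shape[1])
    W = np.linalg.solve(G, Z.T @ T)
    return FeatureDecoder(voxel_indices=idx, weights=W,
                          bias=np.zeros(Y.shape[1]), lam=lam,
                          x_stats=x_stats, y_stats=y_stats, layer=layer,
                          trial_scale_rule=trial_scale_rule)


def fit_decoder_from_dataset(ds: Dataset, k: int | None = None,
                             lam: float = DEFAULT_LAMBDA,
                             **kwargs) -> FeatureDecoder:
    return fit_decoder(ds.voxel_matrix(), ds.target_matrix(), k=k, lam=lam,
                       **kwargs)


def leave_category_out_fit(ds: Dataset, excluded_category: str,
                           k: int | None = None, lam: float = DEFAULT_LAMBDA,
                           **kwargs) -> FeatureDecoder:
    """Fit with every training sample of one category excluded."""
    cats = ds.categories()
    keep = cats != excluded_category
    if not keep.any():
        raise ValueError("excluding this category removes all training data")
    X = ds.voxel_matrix()[keep]
    Y = ds.target_matrix()[keep]
    dec = fit_decoder(X, Y, k=k, lam=lam, **kwargs)
    dec.excluded_category = excluded_category
    return dec
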