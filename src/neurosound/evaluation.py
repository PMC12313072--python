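"""The quantitative evaluation battery.

Profile correlations, pairwise identification (correlation or Euclidean
similarity, all-lure or within-category scopes), identification against
temporally disrupted true candidates, hierarchical-evaluator identification,
8-s block aggregation, attention majority-vote scoring with an exact
binomial test, t-based confidence intervals, and the two prospective power
computations (noncentral-t and exact binomial) whose full-scale-design answers
are N = 27 and N = 37.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import (AcousticSummary, MelSpectrogram, melspectrogram,
                       extract_hierarchy, shuffle_time, texture_surrogate)
from .nnet import LAYER_NAMES, HierarchyNet

#: evaluator stages 1..6 map onto the six hierarchy levels
STAGE_LAYERS = dict(enumerate(LAYER_NAMES, start=1))


@dataclass
class IdentificationOutcome:
    sample_id: str
    n_pairs: int
    n_correct: float          # ties contribute 0.5
    metric: str = "pearson"
    candidate_scope: str = "all"

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_pairs


@dataclass
class BlockScore:
    stimulus_id: str
    accuracy: float


@dataclass
class AttentionOutcome:
    trial_id: str
    correct: bool


@dataclass
class StatResult:
    mean: float | None = None
    ci95_low: float | None = None
    ci95_high: float | None = None
    p_value: float | None = None
    required_n: int | None = None
    effect_size: float | None = None

    def __post_init__(self):
        if self.ci95_low is not None and not (
                self.ci95_low <= self.mean <= self.ci95_high):
            raise ValueError("CI must bracket the mean")


# --------------------------------------------------------------- correlation
def _rankdata(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=0)


def profile_correlation(true: np.ndarray, decoded: np.ndarray,
                        metric: str = "pearson"):
    """Per-unit correlation between true and decoded values across samples.

    Returns (per-unit r with NaN for constant units, mean over valid units,
    number of excluded constant units).
    """
    true = np.atleast_2d(true)
    decoded = np.atleast_2d(decoded)
    if true.shape != decoded.shape:
        raise ValueError("matched samples x units shapes required")
    if true.shape[0] < 3:
        raise ValueError("profile correlation needs at least 3 samples")
    a, b = (true, decoded) if metric == "pearson" else (
        _rankdata(true), _rankdata(decoded))
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    sa = np.sqrt((ac ** 2).sum(axis=0))
    sb = np.sqrt((bc ** 2).sum(axis=0))
    valid = (sa > 1e-12) & (sb > 1e-12)
    r = np.full(true.shape[1], np.nan)
    r[valid] = (ac * bc).sum(axis=0)[valid] / (sa * sb)[valid]
    return r, float(np.nanmean(r)) if valid.any() else np.nan, int((~valid).sum())


def _similarity(a: np.ndarray, b: np.ndarray, metric: str) -> float:
    """Higher-is-more-similar scalar; Euclidean similarity is negated distance."""
    a = np.ravel(np.asarray(a, dtype=np.float64))
    b = np.ravel(np.asarray(b, dtype=np.float64))
    if metric == "euclidean":
        return -float(np.linalg.norm(a - b))
    if metric == "spearman":
        a, b = stats.rankdata(a), stats.rankdata(b)
    ac, bc = a - a.mean(), b - b.mean()
    denom = np.linalg.norm(ac) * np.linalg.norm(bc)
    return float(ac @ bc / denom) if denom > 1e-12 else 0.0


# ------------------------------------------------------------ identification
def pairwise_identification(probe: np.ndarray, candidates: list,
                            true_index: int, metric: str = "pearson",
                            scope: str = "all",
                            categories: list | None = None,
                            sample_id: str = "",
                            true_candidate: np.ndarray | None = None,
                            ) -> IdentificationOutcome | None:
    """One pairwise comparison per lure; ties score 0.5.

    ``candidates`` is the full test pool of feature vectors (index
    ``true_index`` marks the probe's own stimulus); ``scope='within_category'``
    restricts lures to the true stimulus's category. ``true_candidate``
    substitutes a perturbed version of the true stimulus's features while
    lures stay unperturbed. None-valued (undefined) probe or true features
    exclude the sample, returning None; undefined lures are skipped.
    """
    if not 0 <= true_index < len(candidates):
        raise ValueError("true_index outside the candidate pool")
    if len(candidates) < 2:
        raise ValueError("candidate pool must contain at least 2 stimuli")
    if probe is None or _undefined(probe):
        return None
    truth = candidates[true_index] if true_candidate is None else true_candidate
    if truth is None or _undefined(truth):
        return None
    probe = np.ravel(probe)
    if np.ravel(truth).shape != probe.shape:
        raise ValueError("probe/candidate dimension mismatch")
    s_true = _similarity(probe, truth, metric)
    n_pairs = 0
    n_correct = 0.0
    for j, cand in enumerate(candidates):
        if j == true_index:
            continue
        if scope == "within_category":
            if categories is None:
                raise ValueError("within_category scope needs categories")
            if categories[j] != categories[true_index]:
                continue
        if cand is None or _undefined(cand):
            continue
        if np.ravel(cand).shape != probe.shape:
            raise ValueError("probe/candidate dimension mismatch")
        s_lure = _similarity(probe, cand, metric)
        n_pairs += 1
        if s_true > s_lure:
            n_correct += 1.0
        elif s_true == s_lure:
            n_correct += 0.5
    if n_pairs == 0:
        return None
    return IdentificationOutcome(sample_id=sample_id, n_pairs=n_pairs,
                                 n_correct=n_correct, metric=metric,
                                 candidate_scope=scope)


def _undefined(x) -> bool:
    arr = np.asarray(x, dtype=np.float64)
    return bool(np.any(~np.isfinite(arr)))


def summary_vector(s: AcousticSummary, attr: str) -> np.ndarray | None:
    v = getattr(s, attr)
    return None if v is None else np.array([v])


# ----------------------------------------------- hierarchical / perturbed id
def _stage_features(wave_or_spec, evaluator: HierarchyNet, stage: int) -> np.ndarray:
    spec = (wave_or_spec if isinstance(wave_or_spec, MelSpectrogram)
            else melspectrogram(wave_or_spec))
    if stage == 0:       # pixel level
        return spec.values.reshape(-1)
    layer = STAGE_LAYERS[stage]
    return extract_hierarchy(spec, net=evaluator)[layer].values.reshape(-1)


def hierarchical_identification(recon_wave, pool_waves: list,
                                evaluator: HierarchyNet, stage: int,
                                true_index: int, sample_id: str = "",
                                ) -> IdentificationOutcome:
    """Pairwise identification on evaluator features at one of 6 stages.

    The evaluator must be a hierarchy independent of the generation pathway
    (its own seed and, optionally, its own training).
    """
    if stage not in STAGE_LAYERS:
        raise ValueError("stage must be 1..6")
    probe = _stage_features(recon_wave, evaluator, stage)
    cands = [_stage_features(w, evaluator, stage) for w in pool_waves]
    return pairwise_identification(probe, cands, true_index,
                                   metric="pearson", sample_id=sample_id)


def perturbed_identification(recon, pool_specs: list[MelSpectrogram],
                             true_index: int, perturbation: str,
                             seed: int = 0, window_ms: float | None = None,
                             stage: int = 0,
                             evaluator: HierarchyNet | None = None,
                             sample_id: str = "") -> IdentificationOutcome:
    """Identification where only the TRUE candidate is disrupted.

    ``perturbation`` is 'texture' (moment-matched scramble) or 'shuffle'
    (segment permutation at ``window_ms``); lure candidates stay intact.
    ``stage=0`` compares spectrogram pixels, stages 1-6 evaluator features.
    """
    true_spec = pool_specs[true_index]
    if perturbation == "texture":
        pert = texture_surrogate(true_spec, seed=seed)
    elif perturbation == "shuffle":
        if window_ms is None:
            raise ValueError("shuffle perturbation needs window_ms")
        pert = shuffle_time(true_spec, window_ms, seed=seed)
    else:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    if stage == 0:
        probe = (recon.values if isinstance(recon, MelSpectrogram)
                 else melspectrogram(recon).values).reshape(-1)
        cands = [s.values.reshape(-1) for s in pool_specs]
        truth = pert.values.reshape(-1)
    else:
        probe = _stage_features(recon, evaluator, stage)
        cands = [_stage_features(s, evaluator, stage) for s in pool_specs]
        truth = _stage_features(pert, evaluator, stage)
    return pairwise_identification(probe, cands, true_index,
                                   metric="pearson", sample_id=sample_id,
                                   true_candidate=truth)


# ------------------------------------------------------------- aggregation
def block_aggregate(window_outcomes: list[IdentificationOutcome],
                    stimulus_of=lambda o: o.sample_id.rsplit("/", 1)[0],
                    n_windows: int = 3) -> list[BlockScore]:
    """Average the window accuracies of each 8-s stimulus into one point."""
    groups: dict[str, list[float]] = {}
    for o in window_outcomes:
        groups.setdefault(stimulus_of(o), []).append(o.accuracy)
    out = []
    for sid in groups:
        if len(groups[sid]) != n_windows:
            raise ValueError(f"stimulus {sid!r} has {len(groups[sid])} window "
                             f"outcomes, expected {n_windows}")
        out.append(BlockScore(stimulus_id=sid,
                              accuracy=float(np.mean(groups[sid]))))
    return out


def ci95(points) -> StatResult:
    """Mean with a t-based 95% confidence interval."""
    x = np.asarray(points, dtype=np.float64)
    if len(x) < 2:
        raise ValueError("confidence interval needs at least 2 points")
    m = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(len(x)))
    tq = stats.t.ppf(0.975, len(x) - 1)
    return StatResult(mean=m, ci95_low=m - tq * se, ci95_high=m + tq * se)


def bootstrap_ci95(points, n_boot: int = 10_000, seed: int = 0) -> StatResult:
    x = np.asarray(points, dtype=np.float64)
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(n_boot, len(x)), replace=True).mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return StatResult(mean=float(x.mean()), ci95_low=float(lo),
                      ci95_high=float(hi))


# ---------------------------------------------------------------- attention
def attention_evaluate(window_scores: dict[str, list[float]],
                       ) -> tuple[list[AttentionOutcome], StatResult]:
    """Majority-vote trial outcomes and an exact one-sided binomial test.

    ``window_scores`` maps trial id to its three window-level scores
    (1 correct, 0 incorrect, 0.5 tie); a trial is correct when the scores
    sum above 1.5. The p-value tests #correct out of n trials against 0.5.
    """
    outcomes = []
    for tid, scores in window_scores.items():
        if len(scores) != 3:
            raise ValueError(f"trial {tid!r} has {len(scores)} window scores, "
                             "expected 3")
        outcomes.append(AttentionOutcome(trial_id=tid,
                                         correct=sum(scores) > 1.5))
    k = sum(o.correct for o in outcomes)
    n = len(outcomes)
    p = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    return outcomes, StatResult(mean=k / n, p_value=p)


def attention_window_score(recon_features: np.ndarray,
                           attended: np.ndarray, unattended: np.ndarray,
                           metric: str = "pearson") -> float:
    """1 / 0 / 0.5 depending on whether the reconstruction is more similar
    to the attended or the unattended stimulus features."""
    sa = _similarity(recon_features, attended, metric)
    su = _similarity(recon_features, unattended, metric)
    return 1.0 if sa > su else (0.5 if sa == su else 0.0)


# ------------------------------------------------------------------- power
def ttest_power(n: int, d: float, alpha: float = 0.05) -> float:
    """Power of a one-sample, one-sided t-test at effect size d."""
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return float(stats.nct.sf(tcrit, df, d * np.sqrt(n)))


def required_n_ttest(d: float, alpha: float = 0.05, power: float = 0.80,
                     n_max: int = 100_000) -> int:
    """Smallest n giving the one-sided one-sample t-test the target power.

    Computed from the noncentral-t distribution; the study-design call
    (d=0.5, alpha=0.05, power=0.80) returns 27.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if d <= 0:
        raise ValueError("effect size must be positive")
    for n in range(2, n_max + 1):
        if ttest_power(n, d, alpha) >= power:
            return n
    raise ValueError("power unreachable within n_max")


def binomial_critical_k(n: int, p0: float, alpha: float) -> int:
    """Smallest k with P(X >= k | p0) <= alpha."""
    k = int(stats.binom.isf(alpha, n, p0))
    while stats.binom.sf(k - 1, n, p0) > alpha:
        k += 1
    while k >= 1 and stats.binom.sf(k - 2, n, p0) <= alpha:
        k -= 1
    return k


def binomial_power(n: int, p1: float, p0: float = 0.5,
                   alpha: float = 0.05) -> float:
    k = binomial_critical_k(n, p0, alpha)
    return float(stats.binom.sf(k - 1, n, p1))


def required_n_binomial(p1: float, p0: float = 0.5, alpha: float = 0.05,
                        power: float = 0.80, n_max: int = 100_000) -> int:
    """Smallest n whose exact one-sided binomial test reaches the target
    power under p1 (no normal approximation).

    The study-design call (p1=0.7 vs chance 0.5, alpha=0.05, power=0.80)
    returns 37.
    """
    if not p1 > p0:
        raise ValueError("p1 must exceed p0")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    for n in range(1, n_max + 1):
        if binomial_power(n, p1, p0, alpha) >= power:
            return n
    raise ValueError("power unreachable within n_max")


# ------------------------------------------------------------ results tables
def outcomes_table(outcomes: list[IdentificationOutcome]) -> pd.DataFrame:
    rows = [(o.sample_id, o.metric, o.candidate_scope, o.n_pairs,
             o.n_correct, o.accuracy) for o in outcomes if o is not None]
    return pd.DataFrame(rows, columns=["sample_id", "metric", "scope",
                                       "n_pairs", "n_correct", "accuracy"])
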