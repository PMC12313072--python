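"""From stimuli and voxel time series to machine-learning data samples.

Each 8-s stimulus is divided into three overlapping 4-s windows (onsets 0,
2, 4 s); the fMRI sample for a window is the mean of the three volumes
acquired 2-8 s after the window onset (volumes at +2, +4, +6 s at TR = 2 s).
Training presentations stay single-trial; test and attention responses are
averaged over their eight repetitions by default. The full-scale design
arithmetic (1,200 x 4 x 3 = 14,400 training samples, 50 x 3 = 150 test
samples, 24 x 2 x 3 = 144 attention samples) falls out of the same
bookkeeping and is exposed without simulating any data via
:func:`design_manifest`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import dsp
from .synth import TR, SyntheticStimulus, VoxelTimeSeries


@dataclass(frozen=True)
class WindowSpec:
    """Three overlapping half-open 4-s windows inside an 8-s stimulus."""

    length: float = 4.0
    offsets: tuple = (0.0, 2.0, 4.0)
    stimulus_duration: float = 8.0

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("window offsets must be strictly increasing")
        if max(self.offsets) + self.length > self.stimulus_duration + 1e-9:
            raise ValueError("windows must fit inside the stimulus")

    @property
    def n_windows(self) -> int:
        return len(self.offsets)


@dataclass
class DataSample:
    stimulus_id: str
    window_index: int
    voxel_vector: np.ndarray
    target: np.ndarray | None = None
    condition: str = "train"
    n_trials_averaged: int = 1
    repetition: int | None = None
    category: str | None = None


@dataclass
class Dataset:
    samples: list = field(default_factory=list)
    design: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.samples)

    def voxel_matrix(self) -> np.ndarray:
        return np.stack([s.voxel_vector for s in self.samples])

    def target_matrix(self) -> np.ndarray:
        if any(s.target is None for s in self.samples):
            raise ValueError("dataset has samples without targets")
        return np.stack([np.ravel(s.target) for s in self.samples])

    def categories(self) -> np.ndarray:
        return np.array([s.category for s in self.samples])


# ----------------------------------------------------------------- windowing
def window_stimulus(stim: SyntheticStimulus,
                    spec: WindowSpec = WindowSpec()) -> list[np.ndarray]:
    """The stimulus waveform cut into the spec's half-open windows."""
    if stim.duration + 1e-9 < max(spec.offsets) + spec.length:
        raise ValueError(
            f"stimulus of {stim.duration} s cannot host a window at offset "
            f"{max(spec.offsets)} s with length {spec.length} s")
    n_seg = int(round(spec.length * stim.rate))
    segs = []
    for off in spec.offsets:
        i0 = int(round(off * stim.rate))
        segs.append(stim.wave[i0:i0 + n_seg])
    return segs


def volume_average(vts: VoxelTimeSeries, window_onset: float) -> np.ndarray:
    """Mean of the three volumes acquired 2-8 s after the window onset."""
    wanted = window_onset + TR * np.arange(1, 4)  # +2, +4, +6 s
    cols = []
    missing = []
    for t in wanted:
        hit = np.flatnonzero(np.isclose(vts.times, t))
        if len(hit) == 0:
            missing.append(t)
        else:
            cols.append(vts.volumes[:, hit[0]])
    if missing:
        raise ValueError(f"missing volumes at {missing} s after stimulus "
                         f"onset for stimulus {vts.stimulus_id!r}")
    return np.mean(cols, axis=0)


def average_trials(vts_list: Sequence[VoxelTimeSeries]) -> VoxelTimeSeries:
    """Element-wise mean across repeated presentations of one stimulus."""
    ids = {v.stimulus_id for v in vts_list}
    if len(ids) != 1:
        raise ValueError(f"cannot average across different stimuli: {sorted(ids)}")
    shapes = {v.volumes.shape for v in vts_list}
    if len(shapes) != 1:
        raise ValueError("mismatched volume shapes")
    mean = np.mean([v.volumes for v in vts_list], axis=0)
    out = VoxelTimeSeries(stimulus_id=vts_list[0].stimulus_id, repetition=1,
                          volumes=mean, condition=vts_list[0].condition,
                          times=vts_list[0].times.copy())
    out.n_trials_averaged = len(vts_list)
    return out


# ------------------------------------------------------------- design counts
def design_manifest(n_train_stimuli: int = 1200, n_train_reps: int = 4,
                    n_test_stimuli: int = 50, n_attention_pairs: int = 24,
                    n_windows: int = 3, single_trial_test: bool = False,
                    n_test_reps: int = 8) -> pd.DataFrame:
    """Enumerate every data sample of an experiment design.

    Returns one row per sample with columns (condition, stimulus, repetition,
    window). Trial-averaged test/attention samples have repetition 0. The
    full-scale defaults give 14,400 / 150 / 144 rows for the train / test /
    attention conditions.
    """
    rows = []
    for i in range(n_train_stimuli):
        for rep in range(1, n_train_reps + 1):
            for w in range(n_windows):
                rows.append(("train", f"train_{i:04d}", rep, w))
    test_reps = range(1, n_test_reps + 1) if single_trial_test else (0,)
    for i in range(n_test_stimuli):
        for rep in test_reps:
            for w in range(n_windows):
                rows.append(("test", f"test_{i:04d}", rep, w))
    for i in range(n_attention_pairs):
        for side in "ab":
            for w in range(n_windows):
                rows.append(("attention", f"pair_{i:02d}#{side}", 0, w))
    return pd.DataFrame(rows, columns=["condition", "stimulus",
                                       "repetition", "window"])


# --------------------------------------------------------------- dataset build
def build_dataset(stimuli: Sequence[SyntheticStimulus],
                  responses: Sequence[VoxelTimeSeries],
                  spec: WindowSpec = WindowSpec(),
                  target_fn: Callable[[np.ndarray], np.ndarray] | None = None,
                  average: bool = True, condition: str = "train") -> Dataset:
    """Pair windowed stimuli with averaged fMRI volumes as DataSamples.

    ``target_fn`` maps a 4-s waveform segment to the decoding-target array
    for that window (applied per window, so targets never leak across
    windows). ``average=True`` collapses repetitions by trial averaging
    (test/attention default); ``average=False`` keeps every repetition as its
    own sample.
    """
    by_stim: dict[str, list[VoxelTimeSeries]] = {}
    for v in responses:
        by_stim.setdefault(v.stimulus_id, []).append(v)
    stim_by_id = {s.id: s for s in stimuli}
    samples = []
    for sid, series in by_stim.items():
        stim = stim_by_id.get(sid.split("#")[0].split("+")[0]) if sid not in stim_by_id else stim_by_id[sid]
        segments = window_stimulus(stim, spec) if (stim is not None and target_fn) else None
        if average and len(series) > 1:
            series_used = [average_trials(series)]
        else:
            series_used = series
        for v in series_used:
            n_avg = getattr(v, "n_trials_averaged", 1)
            for w, off in enumerate(spec.offsets):
                target = np.ravel(target_fn(segments[w])) if segments is not None else None
                samples.append(DataSample(
                    stimulus_id=sid, window_index=w,
                    voxel_vector=volume_average(v, off), target=target,
                    condition=condition, n_trials_averaged=n_avg,
                    repetition=v.repetition if n_avg == 1 else None,
                    category=stim.category if stim is not None else None))
    n_stim = len(by_stim)
    ds = Dataset(samples=samples, design={
        "condition": condition, "n_stimuli": n_stim,
        "n_windows": spec.n_windows, "averaged": average,
        "n_samples": len(samples)})
    _check_counts(ds, responses, average)
    return ds


def _check_counts(ds: Dataset, responses, average: bool):
    n_stim = ds.design["n_stimuli"]
    n_windows = ds.design["n_windows"]
    if average:
        expected = n_stim * n_windows
    else:
        expected = len(responses) * n_windows
    if len(ds) != expected:
        raise AssertionError(
            f"sample count {len(ds)} violates the design identity "
            f"(expected {expected})")
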