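"""Stimulus-side representations.

Log-mel spectrograms (80 bands, 125-7,600 Hz, hop 256, 4-s input -> 345
frames center-cropped to 336), the convolutional feature hierarchy, a
spectrotemporal modulation filterbank (128 x 40 x 6 x 20), scalar acoustic
descriptors (F0 / spectral centroid / HNR), and the temporally disrupted
control stimuli (moment-matched "texture" surrogates and frame-shuffled
spectrograms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dsp
from .nnet import LAYER_NAMES, LAYER_TEMPORAL, HierarchyNet

SEGMENT_SECONDS = 4.0
SEGMENT_SAMPLES = int(SEGMENT_SECONDS * dsp.SAMPLE_RATE)  # 88,200
N_MELS = 80
N_FRAMES_RAW = 1 + SEGMENT_SAMPLES // dsp.HOP  # 345
N_FRAMES = 336  # after center cropping
MEL_FLOOR = 1e-5
FRAME_MS = 4000.0 / N_FRAMES  # nominal frame duration used for shuffling

_MEL_FB, _MEL_CENTERS = dsp.mel_filterbank(N_MELS)


@dataclass
class MelSpectrogram:
    """Log-magnitude mel spectrogram, shape (80, 336) after cropping."""

    values: np.ndarray
    band_centers: np.ndarray = field(default_factory=lambda: _MEL_CENTERS.copy())
    frame_hop: int = dsp.HOP

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("mel spectrogram contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class LayerFeature:
    """One hierarchy level's activations, shape (units, temporal)."""

    layer: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if self.layer not in LAYER_NAMES:
            raise ValueError(f"unknown layer {self.layer!r}")

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def temporal_length(self) -> int:
        return self.values.shape[1]


@dataclass
class ModulationFeature:
    """Spectrotemporal modulation energies, shape (128, 40, 6, 20)."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (128, 40, 6, 20):
            raise ValueError(f"modulation feature shape {self.values.shape} "
                             "!= (128, 40, 6, 20)")


@dataclass
class AcousticSummary:
    """Scalar descriptors; None marks an undefined (unpitched) estimate."""

    f0_mean: float | None
    sc_median: float | None
    hnr_mean: float | None


# ----------------------------------------------------------------- mel front
def melspectrogram(wave: np.ndarray) -> MelSpectrogram:
    """Log-mel spectrogram of a 4-s, 22,050 Hz waveform.

    STFT with 1,024 bins and hop 256 (345 frames with center padding),
    triangular mel projection onto 80 bands spanning 125-7,600 Hz, log
    compression with floor 1e-5, and a center crop from 345 to 336 frames.
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1 or len(wave) != SEGMENT_SAMPLES:
        raise ValueError(
            f"expected a 4-s waveform of {SEGMENT_SAMPLES} samples at "
            f"{dsp.SAMPLE_RATE} Hz, got shape {wave.shape}")
    power = np.abs(dsp.stft(wave)) ** 2
    assert power.shape[1] == N_FRAMES_RAW
    mel = _MEL_FB @ power
    logmel = np.log(np.maximum(mel, MEL_FLOOR))
    start = (N_FRAMES_RAW - N_FRAMES) // 2
    return MelSpectrogram(values=logmel[:, start:start + N_FRAMES])


def _check_80x336(values: np.ndarray):
    if values.shape != (N_MELS, N_FRAMES):
        raise ValueError(f"expected an (80, 336) spectrogram, got {values.shape}")


# ------------------------------------------------------------------ hierarchy
def extract_hierarchy(spec: MelSpectrogram, net: HierarchyNet | None = None, *,
                      net_seed: int = 0, trained: bool = False,
                      ) -> dict[str, LayerFeature]:
    """Per-layer features of the conv hierarchy for an 80 x 336 spectrogram.

    Either pass a prepared (possibly classification-fitted) ``net``, or let
    one be built from ``net_seed``; ``trained=False`` keeps the seed's random
    weights (the untrained-network control).
    """
    _check_80x336(spec.values)
    if net is None:
        net = HierarchyNet(seed=net_seed)
        if trained:
            raise ValueError("trained=True requires a fitted net; "
                             "call HierarchyNet.fit_classifier first")
    acts = net.forward(spec.values)
    return {name: LayerFeature(layer=name, values=acts[name])
            for name in LAYER_NAMES}


def temporal_downsample(feat: LayerFeature, n_segments: int = 21) -> np.ndarray:
    """Segment-mean pooling of a (units, T) feature map to (units, 21).

    A length-1 (fully connected) input is broadcast to ``n_segments``
    identical columns.
    """
    v = feat.values
    t = v.shape[1]
    if t == 1:
        return np.tile(v, (1, n_segments))
    if n_segments > t:
        raise ValueError(f"cannot pool {t} frames into {n_segments} segments")
    segments = np.array_split(np.arange(t), n_segments)
    return np.stack([v[:, s].mean(axis=1) for s in segments], axis=1)


# ----------------------------------------------------------------- modulation
_N_COCH = 128
_COCH_FMIN, _COCH_FMAX = 180.0, 7040.0
_SPEC_RATES = np.array([0.5, 0.79, 1.26, 2.0, 3.17, 4.0])  # cycles/octave
_TEMP_RATES = np.geomspace(1.0, 30.0, 10)                   # Hz
_ENV_RATE = 200  # Hz, envelope sampling before modulation filtering
_N_OUT_FRAMES = 40


def _cochleagram(wave: np.ndarray, compression: float = 0.3) -> np.ndarray:
    """(128, 800) compressed envelope of log-spaced bandpass channels."""
    n = len(wave)
    X = np.fft.rfft(wave)
    freqs = np.fft.rfftfreq(n, d=1.0 / dsp.SAMPLE_RATE)
    centers = np.geomspace(_COCH_FMIN, _COCH_FMAX, _N_COCH)
    # half-octave cosine-shaped overlapping bands on a log-frequency axis
    logf = np.log2(np.maximum(freqs, 1e-6))
    n_env = int(SEGMENT_SECONDS * _ENV_RATE)
    coch = np.empty((_N_COCH, n_env))
    block = n // n_env
    for i, fc in enumerate(centers):
        d = (logf - np.log2(fc)) / 0.5
        mask = np.where(np.abs(d) < 1.0, np.cos(0.5 * np.pi * d) ** 2, 0.0)
        band = np.fft.irfft(X * mask, n=n)
        env = np.maximum(band, 0.0)  # half-wave rectification
        env = env[: n_env * block].reshape(n_env, block).mean(axis=1)
        coch[i] = env ** compression
    return coch


def _modulation_filter(shape, spec_rate, temp_rate, upward: bool) -> np.ndarray:
    """2-D Fourier-domain directional filter over a (channels, time) array."""
    n_ch, n_t = shape
    oct_per_chan = np.log2(_COCH_FMAX / _COCH_FMIN) / (_N_COCH - 1)
    f_spec = np.fft.fftfreq(n_ch, d=oct_per_chan)[:, None]      # cycles/octave
    f_temp = np.fft.fftfreq(n_t, d=1.0 / _ENV_RATE)[None, :]    # Hz
    with np.errstate(divide="ignore"):
        gs = np.exp(-0.5 * (np.log2(np.abs(f_spec) / spec_rate) / 0.6) ** 2)
        gt = np.exp(-0.5 * (np.log2(np.abs(f_temp) / temp_rate) / 0.6) ** 2)
    gs[f_spec[:, 0] == 0.0, :] = 0.0
    gt[:, f_temp[0] == 0.0] = 0.0
    h = gs * gt
    # an upward-drifting ripple cos(2*pi*(w t - Omega x)) concentrates its
    # energy in the quadrants where temporal and spectral frequency have
    # opposite signs
    sign = -1.0 if upward else 1.0
    quad = (np.sign(f_spec) * np.sign(f_temp)) == sign
    return h * quad


def modulation_features(wave: np.ndarray, compression: float = 0.3) -> ModulationFeature:
    """Spectrotemporal modulation energy, shape (128, 40, 6, 20).

    A 128-channel cochleagram (log-spaced 180-7,040 Hz, half-wave rectified,
    compressed) is filtered by a directional 2-D modulation filterbank with
    6 spectral rates (0.5-4 cyc/oct) and 10 temporal rates (1-30 Hz), each in
    an upward and a downward version, and the filter output envelopes are
    integrated into 40 100-ms frames.
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1 or len(wave) != SEGMENT_SAMPLES:
        raise ValueError("modulation features require a 4-s waveform")
    coch = _cochleagram(wave, compression)
    coch = coch - coch.mean()
    C = np.fft.fft2(coch)
    out = np.empty((_N_COCH, _N_OUT_FRAMES, len(_SPEC_RATES), 20))
    n_env = coch.shape[1]
    block = n_env // _N_OUT_FRAMES
    for si, sr in enumerate(_SPEC_RATES):
        for ti, tr in enumerate(_TEMP_RATES):
            for di, up in enumerate((True, False)):
                H = _modulation_filter(coch.shape, sr, tr, up)
                filt = np.abs(np.fft.ifft2(C * H))
                red = filt[:, : block * _N_OUT_FRAMES]
                red = red.reshape(_N_COCH, _N_OUT_FRAMES, block).mean(axis=2)
                out[:, :, si, di * 10 + ti] = red
    return ModulationFeature(values=out)


# ------------------------------------------------------------------ acoustics
_YIN_FRAME = 2048
_YIN_HOP = 256
_F0_MIN, _F0_MAX = 65.0, 2093.0
_YIN_THRESHOLD = 0.15
_MIN_VOICED = 5


def _yin_frame(frame: np.ndarray) -> tuple[float, float] | None:
    """(f0, periodicity r) of one frame, or None if unvoiced."""
    n = len(frame)
    frame = frame - frame.mean()
    if np.max(np.abs(frame)) < 1e-8:
        return None
    tau_max = int(dsp.SAMPLE_RATE / _F0_MIN)
    tau_min = max(2, int(dsp.SAMPLE_RATE / _F0_MAX))
    # difference function via autocorrelation
    size = 2 * n
    f = np.fft.rfft(frame, size)
    acf = np.fft.irfft(f * np.conj(f), size)[:tau_max + 1]
    cum = np.cumsum(frame ** 2)
    energy = cum[-1]
    tail_energy = energy - np.concatenate(([0.0], cum[:-1]))
    d = tail_energy[: tau_max + 1] + energy - 2 * acf
    d = np.maximum(d, 0.0)
    # cumulative-mean normalization
    cmndf = np.ones_like(d)
    run = np.cumsum(d[1:])
    cmndf[1:] = d[1:] * np.arange(1, tau_max + 1) / np.maximum(run, 1e-12)
    below = np.flatnonzero(cmndf[tau_min:tau_max] < _YIN_THRESHOLD) + tau_min
    if len(below) == 0:
        return None
    # first local minimum within the below-threshold run
    tau = below[0]
    while tau + 1 < tau_max and cmndf[tau + 1] < cmndf[tau]:
        tau += 1
    # parabolic interpolation around tau
    if 1 <= tau < tau_max:
        a, b, c = cmndf[tau - 1], cmndf[tau], cmndf[tau + 1]
        denom = a - 2 * b + c
        shift = 0.5 * (a - c) / denom if abs(denom) > 1e-12 else 0.0
        tau_f = tau + np.clip(shift, -1, 1)
    else:
        tau_f = float(tau)
    r = acf[tau] / max(energy, 1e-12)  # periodicity for HNR
    return dsp.SAMPLE_RATE / tau_f, float(np.clip(r, 1e-6, 1 - 1e-6))


def acoustic_summary(wave: np.ndarray) -> AcousticSummary:
    """Mean F0 (YIN-style tracker), median spectral centroid, mean HNR.

    Unpitched or silent input yields None flags rather than raising; the
    spectral centroid is None only for (near-)silence.
    """
    wave = np.asarray(wave, dtype=np.float64)
    if wave.ndim != 1 or len(wave) == 0:
        raise ValueError("acoustic_summary requires a non-empty 1-D waveform")
    n_frames = max(0, 1 + (len(wave) - _YIN_FRAME) // _YIN_HOP)
    f0s, hnrs = [], []
    for j in range(n_frames):
        res = _yin_frame(wave[j * _YIN_HOP: j * _YIN_HOP + _YIN_FRAME])
        if res is not None:
            f0, r = res
            f0s.append(f0)
            hnrs.append(10.0 * np.log10(r / (1.0 - r)))
    voiced = len(f0s) >= _MIN_VOICED
    mag = np.abs(dsp.stft(wave))
    freqs = np.linspace(0.0, dsp.SAMPLE_RATE / 2.0, mag.shape[0])
    frame_energy = mag.sum(axis=0)
    keep = frame_energy > 1e-8
    if keep.any():
        sc = (freqs[:, None] * mag[:, keep]).sum(axis=0) / frame_energy[keep]
        sc_median = float(np.median(sc))
    else:
        sc_median = None
    return AcousticSummary(
        f0_mean=float(np.mean(f0s)) if voiced else None,
        sc_median=sc_median,
        hnr_mean=float(np.mean(hnrs)) if voiced else None,
    )


# ---------------------------------------------------- temporal perturbations
def texture_surrogate(spec: MelSpectrogram, seed: int) -> MelSpectrogram:
    """A time-scrambled spectrogram with the original's time-averaged moments.

    Independent Gaussian frames are colored and shifted so that each band's
    temporal mean and variance and the inter-band correlation matrix match
    the input exactly, while any temporal autocorrelation beyond lag 0 is
    destroyed. Stands in for full summary-statistics texture synthesis.
    """
    _check_80x336(spec.values)
    x = spec.values
    mu = x.mean(axis=1)
    xc = x - mu[:, None]
    cov = xc @ xc.T / x.shape[1]
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(x.shape)
    z -= z.mean(axis=1, keepdims=True)
    # whiten the sample, then recolor with the target covariance
    cz = z @ z.T / z.shape[1]
    wz = _inv_sqrt_psd(cz)
    ct = _sqrt_psd(cov)
    out = ct @ (wz @ z) + mu[:, None]
    # bands that were exactly constant stay constant
    const = x.std(axis=1) < 1e-12
    out[const] = x[const]
    return MelSpectrogram(values=out, band_centers=spec.band_centers,
                          frame_hop=spec.frame_hop)


def _sqrt_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, 0.0)
    return v @ np.diag(np.sqrt(w)) @ v.T


def _inv_sqrt_psd(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(m)
    w = np.maximum(w, 1e-12)
    return v @ np.diag(1.0 / np.sqrt(w)) @ v.T


def shuffle_time(spec: MelSpectrogram, window_ms: float, seed: int) -> MelSpectrogram:
    """Randomly permute equal-sized temporal segments of a spectrogram.

    Segment length is ``window_ms`` converted to frames (4 s / 336 frames per
    frame); a trailing remainder shorter than one segment stays in place. The
    permutation is redrawn if it would reproduce the original order.
    """
    _check_80x336(spec.values)
    frames_per_seg = int(round(window_ms / FRAME_MS))
    if frames_per_seg < 1:
        raise ValueError(f"window of {window_ms} ms is shorter than one "
                         f"spectrogram frame (~{FRAME_MS:.1f} ms)")
    n_seg = N_FRAMES // frames_per_seg
    if n_seg < 2:
        raise ValueError("window covers the whole spectrogram; a shuffled "
                         "version cannot differ from the original")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_seg)
    while np.array_equal(perm, np.arange(n_seg)):
        perm = rng.permutation(n_seg)
    body = n_seg * frames_per_seg
    segs = spec.values[:, :body].reshape(N_MELS, n_seg, frames_per_seg)
    out = np.concatenate([segs[:, perm].reshape(N_MELS, body),
                          spec.values[:, body:]], axis=1)
    return MelSpectrogram(values=out, band_centers=spec.band_centers,
                          frame_hop=spec.frame_hop)


SHUFFLE_WINDOWS_MS = (12, 24, 48, 96, 190, 286, 500, 1000, 2000)
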