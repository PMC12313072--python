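"""Low-level signal-processing primitives.

Short-time Fourier analysis, mel filterbank projection, Griffin-Lim phase
recovery and non-negative mel inversion, written against numpy/scipy only.
All functions operate on 1-D float waveforms sampled at a fixed rate
(22,050 Hz throughout the package) and are deterministic.
"""

from __future__ import annotations

import numpy as np

SAMPLE_RATE = 22_050
N_FFT = 1024
HOP = 256


def hann(n: int) -> np.ndarray:
    # periodic Hann, the standard analysis window for 75%-overlap STFT
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * np.arange(n) / n)


def frame_signal(wave: np.ndarray, n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    """Center-padded overlapping frames, shape (n_fft, n_frames).

    With center padding the frame count is ``1 + len(wave) // hop``.
    """
    wave = np.asarray(wave, dtype=np.float64)
    pad = n_fft // 2
    padded = np.pad(wave, pad)
    n_frames = 1 + len(wave) // hop
    idx = np.arange(n_fft)[:, None] + hop * np.arange(n_frames)[None, :]
    return padded[idx]


def stft(wave: np.ndarray, n_fft: int = N_FFT, hop: int = HOP) -> np.ndarray:
    """Complex STFT, shape (1 + n_fft//2, n_frames)."""
    frames = frame_signal(wave, n_fft, hop)
    return np.fft.rfft(frames * hann(n_fft)[:, None], axis=0)


def istft(spec: np.ndarray, n_fft: int = N_FFT, hop: int = HOP,
          length: int | None = None) -> np.ndarray:
    """Inverse STFT by windowed overlap-add with squared-window normalization."""
    frames = np.fft.irfft(spec, n=n_fft, axis=0)
    w = hann(n_fft)
    frames = frames * w[:, None]
    n_frames = frames.shape[1]
    total = n_fft + hop * (n_frames - 1)
    out = np.zeros(total)
    wsum = np.zeros(total)
    for j in range(n_frames):
        sl = slice(j * hop, j * hop + n_fft)
        out[sl] += frames[:, j]
        wsum[sl] += w ** 2
    out /= np.maximum(wsum, 1e-10)
    pad = n_fft // 2
    out = out[pad:]
    if length is not None:
        out = out[:length] if len(out) >= length else np.pad(out, (0, length - len(out)))
    return out


def hz_to_mel(f):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int = 80, fmin: float = 125.0, fmax: float = 7600.0,
                   sr: int = SAMPLE_RATE, n_fft: int = N_FFT) -> tuple[np.ndarray, np.ndarray]:
    """Triangular mel filterbank.

    Returns (filters, centers) where filters has shape (n_mels, 1 + n_fft//2)
    and centers are the band center frequencies in Hz.
    """
    n_bins = 1 + n_fft // 2
    fft_freqs = np.linspace(0.0, sr / 2.0, n_bins)
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for i in range(n_mels):
        lo, c, hi = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - lo) / max(c - lo, 1e-12)
        down = (hi - fft_freqs) / max(hi - c, 1e-12)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    # area-normalize each triangle so band energies are comparable
    enorm = 2.0 / (hz_pts[2:] - hz_pts[:-2])
    fb *= enorm[:, None]
    return fb, hz_pts[1:-1]


def nnls_columns(A: np.ndarray, B: np.ndarray, n_iter: int = 400) -> np.ndarray:
    """Solve min ||A X - B||^2 s.t. X >= 0 column-wise by projected gradient.

    Vectorized across all columns of B; step size 1/L with L the squared
    spectral norm of A. Adequate for mel-to-linear spectrogram inversion.
    """
    L = np.linalg.norm(A, 2) ** 2
    X = np.maximum(A.T @ B, 0.0) / max(L, 1e-12)
    AtA = A.T @ A
    AtB = A.T @ B
    step = 1.0 / L
    for _ in range(n_iter):
        X = np.maximum(X - step * (AtA @ X - AtB), 0.0)
    return X


def griffin_lim(magnitude: np.ndarray, n_iter: int = 60, n_fft: int = N_FFT,
                hop: int = HOP, length: int | None = None,
                seed: int = 0) -> np.ndarray:
    """Recover a waveform from an STFT magnitude by Griffin-Lim iterations."""
    rng = np.random.default_rng(seed)
    phase = np.exp(2j * np.pi * rng.random(magnitude.shape))
    spec = magnitude * phase
    n = length if length is not None else hop * (magnitude.shape[1] - 1)
    for _ in range(n_iter):
        x = istft(spec, n_fft, hop, length=n)
        rebuilt = stft(x, n_fft, hop)[:, : magnitude.shape[1]]
        phase = rebuilt / np.maximum(np.abs(rebuilt), 1e-12)
        spec = magnitude * phase
    return istft(spec, n_fft, hop, length=n)
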