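"""Spectral estimation: Welch PSDs and Morlet wavelet coefficients.

Two estimators serve two purposes. Welch periodograms (2.5 s Hann windows,
75% overlap) feed the alpha-peak fitting and summary alpha power. Morlet
wavelet coefficients on a 27-point dyadic grid ``2^(1 + 0.15 k)`` Hz,
k = 0..26 (2 to ~29.9 Hz) with spectral resolution q = f/sigma_f = 4.88
provide the power-spectrum features and the complex samples all
connectivity metrics are built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, welch

from .data import EpochSet

__all__ = ["PSD", "WaveletCoeffs", "SpectralTensor", "welch_psd",
           "morlet_grid", "morlet_transform", "relative_power"]

CONDITIONS = ("EO", "EC")


@dataclass
class PSD:
    """Power spectral density, space x frequency, in µV²/Hz."""

    power: np.ndarray
    freqs: np.ndarray
    condition: str
    channels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(self.power < -1e-12):
            raise ValueError("PSD values must be non-negative")


@dataclass
class WaveletCoeffs:
    """Complex Morlet coefficients, ragged over the frequency grid.

    ``coeffs[k]`` has shape (epochs, spaces, windows_k): window count grows
    with frequency because the window length is 5 sigma_t and the step is
    10% of it. Per-epoch condition labels are carried along so estimators
    can split EO/EC downstream.
    """

    coeffs: list                   # per-frequency arrays
    freqs: np.ndarray
    q: float
    condition: np.ndarray          # per-epoch labels
    channels: list = field(default_factory=list)

    def power(self, condition: str | None = None) -> np.ndarray:
        """Mean |coeff|² over epochs and windows -> spaces x frequencies."""
        if condition is None:
            sel = np.ones(len(self.condition), dtype=bool)
        else:
            sel = self.condition == condition
        if not sel.any():
            raise ValueError(f"no epochs with condition {condition}")
        cols = []
        for c in self.coeffs:
            cols.append(np.mean(np.abs(c[sel]) ** 2, axis=(0, 2)))
        return np.stack(cols, axis=1)


@dataclass
class SpectralTensor:
    """Power indexed by space x frequency x condition."""

    values: np.ndarray
    freqs: np.ndarray
    conditions: tuple = CONDITIONS
    kind: str = "absolute"
    channels: list = field(default_factory=list)


def welch_psd(epochs: EpochSet, window: float = 2.5,
              overlap: float = 0.75) -> PSD:
    """Hann-tapered Welch PSD averaged over segments and epochs.

    With the default 2.5 s window the frequency resolution is 0.4 Hz.
    Density scaling: integrating the PSD over frequency recovers the
    signal variance (Parseval).
    """
    if epochs.n_epochs == 0:
        raise ValueError("no epochs to estimate a PSD from")
    if window > epochs.epoch_length + 1e-9:
        raise ValueError("Welch window longer than the epoch")
    nper = int(round(window * epochs.srate))
    nover = int(round(overlap * nper))
    freqs, pxx = welch(epochs.data, fs=epochs.srate, window="hann",
                       nperseg=nper, noverlap=nover, axis=-1,
                       scaling="density", detrend=False)
    conds = set(epochs.condition.tolist())
    cond = conds.pop() if len(conds) == 1 else "mixed"
    return PSD(power=pxx.mean(axis=0), freqs=freqs, condition=cond,
               channels=list(epochs.channels))


def morlet_grid() -> np.ndarray:
    """The 27-point frequency grid 2^(1 + 0.15 k), k = 0..26 (2 to ~29.9 Hz)."""
    k = np.arange(27)
    return 2.0 ** (1.0 + 0.15 * k)


def _wavelet(freq: float, srate: float, q: float,
             window_sigmas: float) -> np.ndarray:
    """Complex demodulation kernel: Gaussian envelope times carrier.

    Normalised so a unit-amplitude sinusoid at the centre frequency yields
    |coeff|² = 0.5 (i.e. the coefficient power equals the sinusoid's mean
    power a²/2 for amplitude a).
    """
    sigma_f = freq / q
    sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
    n_w = int(round(window_sigmas * sigma_t * srate))
    if n_w < 3:
        raise ValueError(f"window too short at {freq:.2f} Hz for srate {srate}")
    tau = (np.arange(n_w) - (n_w - 1) / 2.0) / srate
    env = np.exp(-(tau ** 2) / (2.0 * sigma_t ** 2))
    kernel = env * np.exp(-2j * np.pi * freq * tau)
    kernel *= np.sqrt(2.0) / env.sum()
    return kernel


def morlet_transform(epochs: EpochSet, q: float = 4.88,
                     window_sigmas: float = 5.0,
                     overlap: float = 0.9,
                     freqs: np.ndarray | None = None) -> WaveletCoeffs:
    """Morlet coefficients at sliding windows within each epoch.

    Windows are ``window_sigmas * sigma_t`` long, stepped by
    ``(1 - overlap)`` of their length, and dropped if they would extend
    past the epoch edge (no padding inside epochs).
    """
    if q <= 0:
        raise ValueError("q must be positive")
    grid = morlet_grid() if freqs is None else np.asarray(freqs, dtype=float)
    n_samp = epochs.data.shape[2]
    out = []
    for f in grid:
        kernel = _wavelet(f, epochs.srate, q, window_sigmas)
        n_w = len(kernel)
        if n_w > n_samp:
            raise ValueError(
                f"wavelet at {f:.2f} Hz ({n_w} samples) exceeds the epoch "
                f"length ({n_samp} samples)")
        step = max(1, int(round((1.0 - overlap) * n_w)))
        # correlation with the kernel: flip for convolution semantics
        conv = fftconvolve(epochs.data, np.conj(kernel[::-1])[None, None, :],
                           mode="valid", axes=2)
        out.append(conv[:, :, ::step].copy())
    return WaveletCoeffs(coeffs=out, freqs=grid, q=q,
                         condition=epochs.condition.copy(),
                         channels=list(epochs.channels))


def relative_power(wc: WaveletCoeffs,
                   conditions: tuple = CONDITIONS) -> SpectralTensor:
    """Relative power spectrum: per space and condition, mean wavelet power
    normalised by its (unweighted) sum over the frequency grid.

    Removes the depth-dependent amplitude bias of beamformer source
    estimates; values per space x condition sum to one over the grid.
    """
    mats = []
    for cond in conditions:
        p = wc.power(cond)                        # space x freq
        total = p.sum(axis=1, keepdims=True)
        if np.any(total <= 0):
            raise ValueError("all-zero power encountered in normalisation")
        mats.append(p / total)
    values = np.stack(mats, axis=2)
    return SpectralTensor(values=values, freqs=wc.freqs.copy(),
                          conditions=tuple(conditions), kind="relative",
                          channels=list(wc.channels))
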