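"""Deterministic preprocessing and subject-inclusion bookkeeping.

Filtering (order-2000 zero-phase FIR band-pass, applied per resting-state
block with 2 s edge padding), polyphase resampling, average re-referencing,
artifact-aware epoching into non-overlapping 2.5 s epochs, bad-channel
interpolation, and the three inclusion criteria used to decide whether a
subject enters the group analyses. Independent-component artifact removal
is a human-in-the-loop step and is represented only by its count, which
criterion (3) consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import fftconvolve, firwin, resample_poly
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .data import Block, EpochSet, Recording

__all__ = ["QualityReport", "bandpass_fir", "resample", "average_reference",
           "epoch", "inclusion_check", "interpolate_bad_channels",
           "largest_bad_neighbourhood", "design_bandpass"]


@dataclass
class QualityReport:
    """Outcome of the three inclusion criteria for one subject."""

    n_epochs_eo: int
    n_epochs_ec: int
    n_usable_channels: int
    max_adjacent_bad: int
    n_good_minus_ics: int
    included: bool
    reasons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def design_bandpass(lo: float, hi: float, order: int, srate: float) -> np.ndarray:
    """Linear-phase Hamming-window FIR band-pass of the given order."""
    if srate <= 2 * hi:
        raise ValueError(f"sampling rate {srate} too low for high edge {hi}")
    return firwin(order + 1, [lo, hi], pass_zero=False, fs=srate,
                  window="hamming")


def bandpass_fir(recording: Recording, lo: float = 1.0, hi: float = 32.0,
                 order: int = 2000, pad: float = 2.0) -> Recording:
    """Zero-phase FIR band-pass applied per resting-state block.

    Each block is extended by ``pad`` seconds on each side (using the
    neighbouring recording samples where available, reflection at the
    recording edges), convolved with the symmetric FIR kernel with
    group-delay compensation, and trimmed back. The symmetric kernel plus
    centred convolution yields an exactly zero-phase response, so filter
    phase cannot bias phase-based connectivity downstream.
    """
    h = design_bandpass(lo, hi, order, recording.srate)
    n_pad = int(round(pad * recording.srate))
    n = recording.n_samples
    out = recording.data.copy()
    for b in recording.blocks:
        i0 = int(round(b.start * recording.srate))
        i1 = min(int(round((b.start + b.duration) * recording.srate)), n)
        if (i1 - i0) + 2 * n_pad < len(h):
            raise ValueError(
                f"block at {b.start:.1f}s too short for order-{order} filter "
                f"with {pad}s padding")
        lo_i, hi_i = max(0, i0 - n_pad), min(n, i1 + n_pad)
        seg = recording.data[:, lo_i:hi_i]
        short_l, short_r = n_pad - (i0 - lo_i), n_pad - (hi_i - i1)
        if short_l > 0 or short_r > 0:  # reflect at recording edges
            seg = np.pad(seg, ((0, 0), (max(short_l, 0), max(short_r, 0))),
                         mode="reflect")
        filt = fftconvolve(seg, h[None, :], mode="same", axes=1)
        out[:, i0:i1] = filt[:, n_pad:n_pad + (i1 - i0)]
    return recording.copy_with(data=out)


def resample(recording: Recording, target: float) -> Recording:
    """Polyphase resampling with anti-alias filtering."""
    if target <= 0:
        raise ValueError("target rate must be positive")
    if abs(target - recording.srate) < 1e-9:
        return recording.copy_with(data=recording.data.copy())
    frac = Fraction(target / recording.srate).limit_denominator(10000)
    data = resample_poly(recording.data, frac.numerator, frac.denominator,
                         axis=1)
    return Recording(data=data, srate=target, channels=list(recording.channels),
                     blocks=list(recording.blocks))


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the instantaneous mean across channels."""
    if epochs.data.shape[1] < 2:
        raise ValueError("average reference requires at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return EpochSet(data, epochs.condition.copy(), epochs.srate,
                    list(epochs.channels), epochs.epoch_length)


def epoch(recording: Recording, length: float = 2.5,
          artifact_mask: list | None = None) -> EpochSet:
    """Tile non-overlapping epochs within each block, skipping artifacts.

    ``artifact_mask`` is a list of ``(onset_s, duration_s)`` intervals; an
    epoch intersecting any interval is dropped. Epochs inherit the block's
    condition; leftover block tails shorter than ``length`` are discarded.
    """
    if length <= 0:
        raise ValueError("epoch length must be positive")
    mask = [(float(o), float(o) + float(d)) for o, d in (artifact_mask or [])]
    n_len = int(round(length * recording.srate))
    chunks, conds = [], []
    for b in recording.blocks:
        t = b.start
        block_end = min(b.start + b.duration, recording.duration)
        while t + length <= block_end + 1e-9:
            t_end = t + length
            if not any(a < t_end - 1e-9 and bnd > t + 1e-9 for a, bnd in mask):
                i0 = int(round(t * recording.srate))
                chunks.append(recording.data[:, i0:i0 + n_len])
                conds.append(b.condition)
            t = t_end
    if not chunks:
        warnings.warn("no clean epochs survive the artifact mask")
        empty = np.empty((0, len(recording.channels), n_len))
        return EpochSet(empty, np.array([], dtype="<U2"), recording.srate,
                        list(recording.channels), length)
    return EpochSet(np.stack(chunks), np.array(conds), recording.srate,
                    list(recording.channels), length)


def largest_bad_neighbourhood(bad: list, positions: np.ndarray,
                              names: list, radius: float = 0.05) -> int:
    """Size of the largest connected component of bad channels.

    Channels are neighbours if their scalp positions are within ``radius``
    meters; this operationalises "more than 3 neighbouring channels
    eliminated" as a contiguous patch of bad electrodes.
    """
    idx = [names.index(b) for b in bad]
    if not idx:
        return 0
    pos = positions[idx]
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    adj = csr_matrix((d <= radius) & (d > 0))
    n_comp, labels = connected_components(adj, directed=False)
    return int(np.bincount(labels).max())


def interpolate_bad_channels(epochs: EpochSet, bad: list,
                             positions: np.ndarray) -> EpochSet:
    """Replace bad channels by spherical-spline interpolation from the rest."""
    from mne.channels.interpolation import _make_interpolation_matrix

    bad_idx = epochs.channel_index(bad)
    good_idx = np.array([i for i in range(len(epochs.channels))
                         if i not in set(bad_idx.tolist())])
    if len(good_idx) < 4:
        raise ValueError("too few good channels for spline interpolation")
    mat = _make_interpolation_matrix(positions[good_idx], positions[bad_idx])
    data = epochs.data.copy()
    data[:, bad_idx, :] = np.einsum("bg,egt->ebt", mat, data[:, good_idx, :])
    return EpochSet(data, epochs.condition.copy(), epochs.srate,
                    list(epochs.channels), epochs.epoch_length)


def inclusion_check(epochs: EpochSet, n_usable_channels: int,
                    max_adjacent_bad: int, n_artifact_ics: int,
                    n_good_channels: int) -> QualityReport:
    """Apply the three subject-inclusion criteria.

    (1) at least 15 clean 2.5 s epochs in each condition; (2) at least 51
    usable channels and no more than 3 neighbouring channels eliminated;
    (3) number of good channels minus artifactual independent components
    at least 35.
    """
    for v in (n_usable_channels, max_adjacent_bad, n_artifact_ics,
              n_good_channels):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n_eo = int(np.sum(epochs.condition == "EO"))
    n_ec = int(np.sum(epochs.condition == "EC"))
    reasons = []
    if min(n_eo, n_ec) < 15:
        reasons.append("epochs")
    if n_usable_channels < 51 or max_adjacent_bad > 3:
        reasons.append("channels")
    good_minus = n_good_channels - n_artifact_ics
    if good_minus < 35:
        reasons.append("components")
    return QualityReport(
        n_epochs_eo=n_eo, n_epochs_ec=n_ec,
        n_usable_channels=n_usable_channels,
        max_adjacent_bad=max_adjacent_bad,
        n_good_minus_ics=good_minus,
        included=not reasons, reasons=reasons)
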