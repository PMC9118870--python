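"""Core in-memory containers shared across the pipeline.

Conventions: signals are in microvolts, time in seconds, frequencies in Hz.
A :class:`Recording` is a continuous multichannel trace organised in
alternating eyes-open (``"EO"``) / eyes-closed (``"EC"``) blocks; an
:class:`EpochSet` is the epoched view used by all spectral estimators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Occipital channels used for the summary alpha measures.
OCCIPITAL = ("O1", "O2", "Oz", "PO4", "PO3", "POz")

#: Default 61-channel 10-10 montage (superset of the 10-20 layout).
CHANNELS_61 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)

#: Compact 23-channel montage (10-20 plus the occipital set) for fast demos.
CHANNELS_DEMO = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
) + ("Oz", "PO3", "POz", "PO4")  # occipital set required by alpha metrics


@dataclass(frozen=True)
class Block:
    """One resting-state block: condition, onset and duration in seconds."""

    condition: str  # "EO" or "EC"
    start: float
    duration: float


def default_blocks(block_len: float = 30.0, total: float = 240.0) -> list[Block]:
    """Alternating 30 s EO/EC blocks totalling 4 minutes (2 min each)."""
    blocks, t, cond = [], 0.0, "EO"
    while t + block_len <= total + 1e-9:
        blocks.append(Block(cond, t, block_len))
        cond = "EC" if cond == "EO" else "EO"
        t += block_len
    return blocks


@dataclass
class Recording:
    """Continuous multichannel EEG trace with block annotations."""

    data: np.ndarray          # channels x samples, µV
    srate: float              # Hz
    channels: list[str]
    blocks: list[Block]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise ValueError("data must be channels x samples matching channel list")
        ends = 0.0
        for b in sorted(self.blocks, key=lambda b: b.start):
            if b.start < ends - 1e-9:
                raise ValueError("blocks overlap")
            ends = b.start + b.duration

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.srate

    def copy_with(self, **kw) -> "Recording":
        return replace(self, **kw)


@dataclass
class EpochSet:
    """Fixed-length epochs with per-epoch condition labels.

    ``data`` is epochs x channels x samples; every epoch has the same length
    and never spans a block boundary.
    """

    data: np.ndarray
    condition: np.ndarray     # per-epoch "EO"/"EC"
    srate: float
    channels: list[str]
    epoch_length: float = 2.5

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if len(self.condition) != self.data.shape[0]:
            raise ValueError("one condition label per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, condition: str) -> "EpochSet":
        mask = self.condition == condition
        return EpochSet(self.data[mask], self.condition[mask], self.srate,
                        list(self.channels), self.epoch_length)

    def channel_index(self, names: Sequence[str]) -> np.ndarray:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return np.array([self.channels.index(n) for n in names])


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject covariates used by the group-level models."""

    id: str
    group: str                # "ASD" or "NT"
    age: float                # years, within [6, 32]
    sex: str                  # "M" or "F"
    iq: float                 # full-scale IQ, > 75 by inclusion rule
    site: str
    medication: bool = False

    def __post_init__(self) -> None:
        if self.group not in ("ASD", "NT"):
            raise ValueError(f"group must be ASD or NT, got {self.group}")
        if not 6.0 <= self.age <= 32.0:
            raise ValueError(f"age {self.age} outside the [6, 32] inclusion range")
        if self.iq <= 75:
            raise ValueError(f"IQ {self.iq} violates the IQ > 75 inclusion rule")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be M or F, got {self.sex}")


def age_group(age: float) -> str:
    """Children 6-11, adolescents 12-17, adults 18+."""
    if age < 12:
        return "child"
    if age < 18:
        return "adolescent"
    return "adult"


def channel_positions(names: Sequence[str]) -> np.ndarray:
    """3D positions (meters) for standard 10-05 channel names via MNE."""
    import mne

    try:  # montage renamed across MNE versions
        montage = mne.channels.make_standard_montage("colin27_1005")
    except Exception:
        montage = mne.channels.make_standard_montage("standard_1005")
    pos = montage.get_positions()["ch_pos"]
    out = []
    for n in names:
        if n not in pos:
            raise KeyError(f"no standard position for channel {n}")
        out.append(pos[n])
    return np.asarray(out, dtype=float)
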