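"""File interfaces: EDF recordings, covariate tables, tensors, reports.

Recordings are written as EDF (16-bit, one data record per second) with a
sidecar TSV of block annotations; reading goes through MNE so BrainVision
(.vhdr/.vmrk/.eeg) files are accepted transparently. Tabular interfaces
are TSV, structured results JSON/YAML, and dense tensors HDF5 with
dimension labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .connectivity import FCTensor
from .data import Block, Recording, SubjectMeta
from .spectral import SpectralTensor

__all__ = ["write_edf", "read_raw", "write_blocks_tsv", "read_blocks_tsv",
           "write_covariates_tsv", "read_covariates_tsv", "write_cohort",
           "cohort_spec_to_yaml", "cohort_spec_from_yaml",
           "write_spectral_h5", "read_spectral_h5", "write_fc_h5",
           "read_fc_h5", "write_json"]


def write_edf(path, recording: Recording) -> None:
    """Minimal EDF writer: int16 samples, 1 s data records.

    The sampling rate must be an integer; physical scaling is per channel
    from the data range. Block annotations go to the sidecar TSV (see
    :func:`write_blocks_tsv`), keeping the signal file plain EDF.
    """
    path = Path(path)
    sr = recording.srate
    if abs(sr - round(sr)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    sr = int(round(sr))
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = n_samp // sr
    if n_rec * sr != n_samp:
        data = data[:, : n_rec * sr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.maximum(pmax - pmin, 1e-6)
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / span
    digital = np.clip(np.round((data - pmin[:, None]) * scale[:, None])
                      + dmin, dmin, dmax).astype("<i2")

    def f(x, width):
        s = str(x)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X", 80), f("X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(256 + 256 * n_ch, 8), f("", 44), f(n_rec, 8), f("1", 8),
        f(n_ch, 4),
    ])
    sig = b"".join([
        b"".join(f(c, 16) for c in recording.channels),
        b"".join(f("EEG", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(f"{pmin[c]:.6g}"[:8], 8) for c in range(n_ch)),
        b"".join(f(f"{pmax[c]:.6g}"[:8], 8) for c in range(n_ch)),
        b"".join(f(dmin, 8) for _ in range(n_ch)),
        b"".join(f(dmax, 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(sr, 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * sr:(r + 1) * sr].tobytes())


def write_blocks_tsv(path, blocks: list[Block]) -> None:
    pd.DataFrame([{"condition": b.condition, "onset": b.start,
                   "duration": b.duration} for b in blocks]
                 ).to_csv(path, sep="\t", index=False)


def read_blocks_tsv(path) -> list[Block]:
    df = pd.read_csv(path, sep="\t")
    return [Block(r.condition, float(r.onset), float(r.duration))
            for r in df.itertuples()]


def read_raw(path, blocks: list[Block] | None = None) -> Recording:
    """Read an EDF or BrainVision file into a :class:`Recording` via MNE.

    Block annotations come from a ``<stem>_blocks.tsv`` sidecar if present,
    from the ``blocks`` argument, or from in-file annotations labelled
    EO/EC.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported raw format: {path.suffix}")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    if blocks is None:
        sidecar = path.with_name(path.stem + "_blocks.tsv")
        if sidecar.exists():
            blocks = read_blocks_tsv(sidecar)
        else:
            blocks = [Block(str(d), float(o), float(du)) for o, du, d in
                      zip(raw.annotations.onset, raw.annotations.duration,
                          raw.annotations.description)
                      if str(d) in ("EO", "EC")]
    if not blocks:
        blocks = [Block("EO", 0.0, raw.times[-1] + 1.0 / raw.info["sfreq"])]
    return Recording(data=data, srate=float(raw.info["sfreq"]),
                     channels=list(raw.ch_names), blocks=blocks)


def write_covariates_tsv(path, metas: list[SubjectMeta]) -> None:
    pd.DataFrame([m.__dict__ for m in metas]).to_csv(path, sep="\t",
                                                     index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"id", "group", "age", "sex", "iq", "site", "medication"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"covariate TSV missing columns: {sorted(missing)}")
    return df


def cohort_spec_to_yaml(spec, path) -> None:
    from .cohort import CohortSpec, CouplingSpec

    d = dict(spec.__dict__)
    d["channels"] = list(d["channels"])
    d["coupling_plan"] = [dict(c.__dict__) for c in d["coupling_plan"]]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def cohort_spec_from_yaml(path):
    from .cohort import CohortSpec, CouplingSpec

    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["coupling_plan"] = [CouplingSpec(**c) for c in d.get("coupling_plan", [])]
    return CohortSpec(**d)


def write_cohort(directory, metas: list[SubjectMeta],
                 recordings: list[Recording], spec=None) -> None:
    """Write a full cohort: per-subject EDF + blocks TSV, covariates, spec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for meta, rec in zip(metas, recordings):
        write_edf(directory / f"{meta.id}.edf", rec)
        write_blocks_tsv(directory / f"{meta.id}_blocks.tsv", rec.blocks)
    write_covariates_tsv(directory / "covariates.tsv", metas)
    if spec is not None:
        cohort_spec_to_yaml(spec, directory / "cohort_spec.yaml")


def write_spectral_h5(path, tensor: SpectralTensor) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=tensor.values)
        fh.create_dataset("freqs", data=tensor.freqs)
        fh.attrs["kind"] = tensor.kind
        fh.attrs["conditions"] = list(tensor.conditions)
        fh.attrs["channels"] = list(tensor.channels)


def read_spectral_h5(path) -> SpectralTensor:
    with h5py.File(path, "r") as fh:
        return SpectralTensor(
            values=fh["values"][()], freqs=fh["freqs"][()],
            conditions=tuple(fh.attrs["conditions"]),
            kind=str(fh.attrs["kind"]),
            channels=[str(c) for c in fh.attrs["channels"]])


def write_fc_h5(path, tensor: FCTensor) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=tensor.values)
        fh.create_dataset("links", data=tensor.links)
        fh.create_dataset("freqs", data=tensor.freqs)
        fh.attrs["conditions"] = list(tensor.conditions)
        fh.attrs["metrics"] = list(tensor.metrics)
        fh.attrs["channels"] = list(tensor.channels)


def read_fc_h5(path) -> FCTensor:
    with h5py.File(path, "r") as fh:
        return FCTensor(
            values=fh["values"][()], links=fh["links"][()],
            freqs=fh["freqs"][()],
            conditions=tuple(fh.attrs["conditions"]),
            metrics=tuple(fh.attrs["metrics"]),
            channels=[str(c) for c in fh.attrs["channels"]])


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
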