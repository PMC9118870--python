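"""Synthetic resting-state EEG cohort generator.

Emulates the data structure of a multi-site case-control resting-state
study: per subject, ~4 minutes of multichannel EEG in alternating 30 s
eyes-open / eyes-closed blocks, built from a 1/f^chi background plus a
narrowband alpha oscillation whose peak frequency increases with age and
whose power is boosted with eyes closed (controlled reactivity). Group
mean/variance effects, per-site offsets and lagged pairwise coupling are
injected with known ground truth so every downstream stage of the pipeline
can be validated against what was put in.

The generator deliberately omits volume conduction, ocular/muscle
artifacts and MRI-based head modelling; it produces sensor-space signals
whose *statistical* structure (covariates, 1/f + alpha spectra, reactivity,
site offsets, coupling) matches the analysis assumptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import hilbert

from .data import (CHANNELS_61, OCCIPITAL, Block, Recording, SubjectMeta,
                   default_blocks)

__all__ = [
    "CouplingSpec", "CohortSpec", "generate_cohort", "generate_leadfield",
    "make_coupled_pair", "shaped_noise", "narrowband_noise",
]


@dataclass(frozen=True)
class CouplingSpec:
    """One injected lagged coupling between a pair of channels.

    ``lag`` is the phase lag in radians in (-pi, pi]; ``env_corr`` controls
    the fraction of the shared analytic signal in the second channel (their
    amplitude envelopes correlate increasingly with it); ``snr`` scales the
    coupled component relative to the background power in its band;
    ``group_snr_delta`` adds a relative SNR difference for the ASD group
    (+d/2 for ASD, -d/2 for NT) so a group contrast can be injected on one
    link.
    """

    ch_a: str
    ch_b: str
    freq: float               # Hz
    lag: float                # radians, in (-pi, pi]
    env_corr: float = 1.0
    snr: float = 1.0
    group_snr_delta: float = 0.0

    def __post_init__(self) -> None:
        if not (-np.pi < self.lag <= np.pi):
            raise ValueError(f"lag {self.lag} outside (-pi, pi]")
        if self.snr <= 0:
            raise ValueError("coupling snr must be positive")
        if not 0.0 <= self.env_corr <= 1.0:
            raise ValueError("env_corr must lie in [0, 1]")


@dataclass
class CohortSpec:
    """Ground-truth parameters of a synthetic cohort.

    Defaults encode the emulated study conditions: 61-channel, 4-minute
    recordings in 30 s alternating EO/EC blocks, ages uniform in [6, 32],
    ~72% male, IQ ~ N(106, 14) truncated above 75, a 1/f background with
    chi = 1, and an age-dependent alpha peak f_p = 8 + 0.1 (age - 6) Hz
    capped at 11 Hz.
    """

    n_per_group: int = 20
    effect_mean: float = 0.0            # standardized d on log alpha power (ASD - NT)
    effect_variance_ratio: float = 1.0  # ASD/NT residual SD ratio on log alpha power
    age_slope_by_group: dict = field(
        default_factory=lambda: {"NT": 0.012, "ASD": 0.004})  # reactivity / year
    coupling_plan: list = field(default_factory=list)
    site_offsets: dict = field(
        default_factory=lambda: {"A": 0.15, "B": 0.0, "C": -0.15})  # log-power
    seed: int = 0
    srate: float = 256.0
    channels: Sequence[str] = CHANNELS_61
    block_len: float = 30.0
    total_duration: float = 240.0
    background_chi: float = 1.0
    background_rms: float = 8.0         # µV
    alpha_rms_ec: float = 6.0           # µV, occipital alpha at eyes closed
    alpha_bandwidth: float = 1.0        # Hz
    reactivity_base: float = 0.45
    reactivity_sd: float = 0.10
    log_power_sd: float = 0.4           # subject-level residual SD (natural log)

    def __post_init__(self) -> None:
        if self.effect_variance_ratio <= 0:
            raise ValueError("effect_variance_ratio must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for c in self.coupling_plan:
            if not isinstance(c, CouplingSpec):
                raise TypeError("coupling_plan entries must be CouplingSpec")
        for g in ("ASD", "NT"):
            if g not in self.age_slope_by_group:
                raise ValueError(f"age_slope_by_group missing group {g}")


def peak_frequency(age: float) -> float:
    """Default alpha peak frequency trajectory: 8 + 0.1 (age-6), capped at 11 Hz."""
    return min(8.0 + 0.1 * (age - 6.0), 11.0)


def shaped_noise(n: int, srate: float, chi: float, rng: np.random.Generator,
                 rms: float = 1.0) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f^chi via inverse-FFT shaping."""
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-chi / 2.0)
    phases = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    x = np.fft.irfft(amp * phases, n=n)
    x *= rms / max(np.std(x), 1e-30)
    return x


def narrowband_noise(n: int, srate: float, f0: float, bandwidth: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to f0 +- bandwidth/2 (FFT mask)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / srate)
    # raised-cosine edges one bin wide keep the envelope smooth
    lo, hi = f0 - bandwidth / 2.0, f0 + bandwidth / 2.0
    mask = ((freqs >= lo) & (freqs <= hi)).astype(float)
    x = np.fft.irfft(spec * mask, n=n)
    x /= max(np.std(x), 1e-30)
    return x


def make_coupled_pair(n: int, srate: float, freq: float, lag: float,
                      env_corr: float = 1.0, seed: int = 0,
                      bandwidth: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free pair of narrowband signals with a fixed phase lag.

    Channel b lags channel a by ``lag`` radians; with ``env_corr < 1`` an
    independent narrowband component is mixed into b, lowering both its
    envelope correlation and phase consistency with a.
    """
    rng = np.random.default_rng(seed)
    a = narrowband_noise(n, srate, freq, bandwidth, rng)
    za = hilbert(a)
    zb = np.sqrt(env_corr) * za
    if env_corr < 1.0:
        indep = hilbert(narrowband_noise(n, srate, freq, bandwidth, rng))
        zb = zb + np.sqrt(1.0 - env_corr) * indep
    b = np.real(zb * np.exp(-1j * lag))
    return a, b


def _subject_meta(spec: CohortSpec, rng: np.random.Generator, idx: int,
                  group: str, sites: list[str]) -> SubjectMeta:
    age = rng.uniform(6.0, 32.0)
    sex = "M" if rng.random() < 0.72 else "F"
    iq = 0.0
    while iq <= 75.0:  # truncated normal by rejection; mean 106, SD 14
        iq = rng.normal(106.0, 14.0)
    site = sites[idx % len(sites)]  # cyclic: every site gets both groups
    med_p = 0.37 if group == "ASD" else 0.056
    return SubjectMeta(id=f"sub-{group}-{idx:03d}", group=group, age=age,
                       sex=sex, iq=iq, site=site,
                       medication=bool(rng.random() < med_p))


def _block_gain(blocks: list[Block], srate: float, n: int,
                gain_eo: float, gain_ec: float) -> np.ndarray:
    g = np.zeros(n)
    for b in blocks:
        i0 = int(round(b.start * srate))
        i1 = min(int(round((b.start + b.duration) * srate)), n)
        g[i0:i1] = gain_eo if b.condition == "EO" else gain_ec
    return g


def generate_cohort(spec: CohortSpec, return_truth: bool = False,
                    signals: bool = True):
    """Generate covariates and recordings for a full synthetic cohort.

    Deterministic given ``spec.seed``; each subject draws from its own
    seeded substream so cohorts are reproducible independent of iteration
    order. Returns ``(metas, recordings)`` with subjects ordered ASD
    block first, then NT; with ``return_truth=True`` a third element
    holds the realized per-subject ground truth (alpha peak frequency,
    reactivity target, alpha log-power) for recovery checks.

    ``signals=False`` skips EEG synthesis (recordings come back empty)
    and draws only the subject-level parameters — a fast mode for
    statistical calibration studies that need many cohorts. Parameters
    are drawn before any signal synthesis, so covariates and ground
    truth are identical across the two modes.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_total = 2 * spec.n_per_group
    streams = [np.random.default_rng(s) for s in ss.spawn(n_total)]
    sites = sorted(spec.site_offsets)
    blocks = default_blocks(spec.block_len, spec.total_duration)
    n_samp = int(round(spec.total_duration * spec.srate))
    channels = list(spec.channels)
    occ_idx = [channels.index(c) for c in OCCIPITAL if c in channels]
    if not occ_idx:
        raise ValueError("channel set must include at least one occipital channel")
    ch_index = {c: i for i, c in enumerate(channels)}
    for cp in spec.coupling_plan:
        for ch in (cp.ch_a, cp.ch_b):
            if ch not in ch_index:
                raise ValueError(f"coupling channel {ch} not in channel set")

    metas: list[SubjectMeta] = []
    recs: list[Recording] = []
    truth: list[dict] = []
    subj = 0
    for group in ("ASD", "NT"):
        for k in range(spec.n_per_group):
            rng = streams[subj]
            meta = _subject_meta(spec, rng, k, group, sites)
            metas.append(meta)

            # subject-level alpha log-power: site offset + group mean shift
            # (effect_mean in units of the subject SD) + heteroscedastic noise
            sd = spec.log_power_sd * (spec.effect_variance_ratio
                                      if group == "ASD" else 1.0)
            shift = spec.effect_mean * spec.log_power_sd if group == "ASD" else 0.0
            logp = (2.0 * np.log(spec.alpha_rms_ec)
                    + spec.site_offsets[meta.site] + shift + rng.normal(0.0, sd))
            amp_ec = np.exp(logp / 2.0)

            slope = spec.age_slope_by_group[meta.group]
            r = (spec.reactivity_base + slope * (meta.age - 19.0)
                 + rng.normal(0.0, spec.reactivity_sd))
            r = float(np.clip(r, 0.02, 0.95))
            amp_eo = amp_ec * np.sqrt(1.0 - r)
            f_p = peak_frequency(meta.age)
            truth.append(dict(id=meta.id, f_p=f_p, r_target=r,
                              log_alpha_power=logp, amp_ec=amp_ec))
            subj += 1
            if not signals:
                continue

            data = np.empty((len(channels), n_samp))
            for c in range(len(channels)):
                data[c] = shaped_noise(n_samp, spec.srate, spec.background_chi,
                                       rng, rms=spec.background_rms)

            # independent alpha realizations per occipital channel: the
            # occipital average then damps envelope sampling noise, keeping
            # per-subject reactivity close to its target over 2 min
            gain = _block_gain(blocks, spec.srate, n_samp, amp_eo, amp_ec)
            for c in occ_idx:
                alpha = narrowband_noise(n_samp, spec.srate, f_p,
                                         spec.alpha_bandwidth, rng)
                data[c] += gain * alpha

            for cp in spec.coupling_plan:
                snr = cp.snr * (1.0 + (0.5 if group == "ASD" else -0.5)
                                * cp.group_snr_delta)
                a, b = make_coupled_pair(
                    n_samp, spec.srate, cp.freq, cp.lag, cp.env_corr,
                    seed=int(rng.integers(2**31)), bandwidth=spec.alpha_bandwidth)
                w = snr * spec.background_rms * 0.5
                data[ch_index[cp.ch_a]] += w * a
                data[ch_index[cp.ch_b]] += w * b

            recs.append(Recording(data=data, srate=spec.srate,
                                  channels=list(channels), blocks=list(blocks)))
    if return_truth:
        import pandas as pd

        return metas, recs, pd.DataFrame(truth)
    return metas, recs


# ---------------------------------------------------------------------------
# synthetic leadfield


def _diamond_grid(spacing_mm: float, radius_mm: float) -> np.ndarray:
    """Cubic-diamond-style grid (checkerboard sublattice of a cubic grid)
    inside a sphere, symmetric about the x = 0 midline."""
    half = int(np.ceil(radius_mm / spacing_mm)) + 1
    idx = np.arange(-half, half + 1)
    ii, jj, kk = np.meshgrid(idx, idx, idx, indexing="ij")
    keep = (ii + jj + kk) % 2 == 0
    pts = np.stack([ii[keep], jj[keep], kk[keep]], axis=1) * spacing_mm
    pts = pts[np.linalg.norm(pts, axis=1) <= radius_mm]
    return pts.astype(float)


def generate_leadfield(n_sensors: int, n_sources: int, seed: int = 0,
                       spacing_mm: float = 15.0):
    """Synthetic gain matrix and mirror-symmetric source grid.

    Sources sit on a 1.5 cm cubic-diamond-style grid inside a spherical
    brain volume, selected nearest-first in mirror orbits so the final set
    stays symmetric about x = 0 (odd counts are completed with a midline
    point). Gains follow the infinite homogeneous-medium dipole potential
    at sensors placed on the upper scalp hemisphere, which makes each
    source's 3-column gain block full rank for generic geometry.
    """
    from .source import Leadfield  # deferred to avoid an import cycle

    if n_sensors < 3:
        raise ValueError("need at least 3 sensors")
    if n_sources < 1:
        raise ValueError("need at least 1 source")

    # grow the sphere until enough grid points exist
    radius = 70.0
    pts = _diamond_grid(spacing_mm, radius)
    while len(pts) < n_sources + 2:
        radius *= 1.2
        pts = _diamond_grid(spacing_mm, radius)

    # group into mirror orbits across x=0 and add nearest-first
    order = np.argsort(np.linalg.norm(pts, axis=1), kind="stable")
    pts = pts[order]
    seen: set[tuple] = set()
    chosen: list[np.ndarray] = []
    singletons: list[np.ndarray] = []  # midline points held back for parity
    for p in pts:
        key = tuple(np.round(p, 6))
        if key in seen:
            continue
        mirror = p * np.array([-1.0, 1.0, 1.0])
        mkey = tuple(np.round(mirror, 6))
        seen.add(key)
        seen.add(mkey)
        if key == mkey:  # midline
            singletons.append(p)
            continue
        if len(chosen) + 2 <= n_sources:
            chosen.extend([p, mirror])
    while len(chosen) < n_sources and singletons:
        chosen.append(singletons.pop(0))
    if len(chosen) < n_sources:
        raise ValueError("could not build a symmetric grid of the requested size")
    positions = np.asarray(chosen[:n_sources])

    # sensors on the upper hemisphere of a 95 mm scalp sphere, jittered
    rng = np.random.default_rng(seed)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_sensors)
    z = 0.15 + 0.85 * (k + 0.5) / n_sensors            # upper cap
    theta = golden * k + 0.05 * rng.standard_normal(n_sensors)
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    sensors = 95.0 * np.stack([rho * np.cos(theta), rho * np.sin(theta), z],
                              axis=1)

    # homogeneous-medium dipole potential: V = e . (s - r) / |s - r|^3
    diff = sensors[:, None, :] - positions[None, :, :]      # sens x src x 3
    dist = np.linalg.norm(diff, axis=2)
    if np.any(dist < 1e-6):
        raise ValueError("a source coincides with a sensor")
    gain = diff / dist[:, :, None] ** 3
    gain *= 1e4  # arbitrary overall scale, keeps numbers O(1)

    for s in range(n_sources):
        if np.linalg.matrix_rank(gain[:, s, :]) < 3:
            raise ValueError(f"rank-deficient gain for source {s}")
    return Leadfield(gain=gain, positions=positions, spacing=spacing_mm)
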