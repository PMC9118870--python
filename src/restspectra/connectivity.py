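"""Spectral connectivity metrics from Morlet wavelet coefficients.

Six pairwise metrics over unordered space pairs (links): the weighted
phase lag index (wPLI, with the epoch-subsampling estimator that removes
sample-size bias), orthogonalized power correlations (orthPowCorr), and
four control metrics — direct power correlations (PowCorr), coherence
(COH), imaginary coherence (iCOH) and the phase locking value (PLV).
wPLI and iCOH discard zero-lag coupling and are therefore insensitive to
volume conduction; orthPowCorr removes the shared zero-lag component
before correlating power envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import WaveletCoeffs

__all__ = ["FCTensor", "cross_spectrum", "wpli", "wpli_subsampled",
           "orth_pow_corr", "control_metrics", "fc_tensor", "METRICS"]

METRICS = ("wPLI", "orthPowCorr", "PowCorr", "COH", "iCOH", "PLV")

_EPS = 1e-30


@dataclass
class FCTensor:
    """Connectivity values, link x frequency x condition x metric."""

    values: np.ndarray
    links: np.ndarray          # n_links x 2, space indices with i < j
    freqs: np.ndarray
    conditions: tuple
    metrics: tuple
    channels: list = field(default_factory=list)

    def metric(self, name: str) -> np.ndarray:
        return self.values[..., self.metrics.index(name)]


def cross_spectrum(c_i: np.ndarray, c_j: np.ndarray) -> np.ndarray:
    """Per-sample cross-spectral values X = c_i conj(c_j)."""
    c_i = np.ravel(np.asarray(c_i))
    c_j = np.ravel(np.asarray(c_j))
    if c_i.shape != c_j.shape:
        raise ValueError("coefficient series must have equal length")
    return c_i * np.conj(c_j)


def wpli(x: np.ndarray) -> float:
    """Weighted phase lag index |mean Im X| / mean |Im X| in [0, 1].

    Returns 0 when the imaginary cross-spectrum vanishes identically
    (e.g. zero-lag identical signals), by convention.
    """
    x = np.ravel(x)
    im = np.imag(x)
    if im.size < 2:
        raise ValueError("need at least 2 cross-spectral samples")
    denom = np.mean(np.abs(im))
    # relative guard: Im X that is pure rounding noise counts as zero
    if denom <= 1e-12 * max(np.mean(np.abs(x)), _EPS):
        return 0.0
    return float(abs(np.mean(im)) / denom)


def wpli_subsampled(x_by_epoch: np.ndarray, n_epochs: int = 15,
                    n_reps: int = 100, seed: int = 0) -> float:
    """Fixed-sample-size wPLI: average over random 15-epoch draws.

    wPLI is positively biased for small sample sizes; estimating it on a
    fixed number of epochs drawn without replacement (and averaging over
    ``n_reps`` draws) keeps the bias identical across subjects with
    different amounts of clean data.

    ``x_by_epoch``: cross-spectral samples as an (epochs, samples) array
    or a list of per-epoch sample arrays.
    """
    epochs = [np.ravel(np.asarray(e)) for e in x_by_epoch]
    n_avail = len(epochs)
    if n_avail < n_epochs:
        raise ValueError(
            f"only {n_avail} epochs available, {n_epochs} required")
    sums = np.array([np.sum(np.imag(e)) for e in epochs])
    abs_sums = np.array([np.sum(np.abs(np.imag(e))) for e in epochs])
    rng = np.random.default_rng(seed)
    vals = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.choice(n_avail, size=n_epochs, replace=False)
        denom = abs_sums[pick].sum()
        vals[r] = abs(sums[pick].sum()) / denom if denom > _EPS else 0.0
    return float(vals.mean())


def _log_orth_power(c_ref: np.ndarray, c_other: np.ndarray) -> np.ndarray:
    """log power of c_other after per-sample orthogonalization on c_ref.

    Residual power below rounding noise (relative to the signal scale) is
    clamped to one constant so identical signals come out exactly
    degenerate instead of correlating their rounding errors.
    """
    y = np.imag(c_other * np.conj(c_ref)) / np.maximum(np.abs(c_ref), _EPS)
    floor = max((1e-10 * np.sqrt(np.mean(np.abs(c_other) ** 2))) ** 2, _EPS)
    return np.log(np.maximum(y ** 2, floor))


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    # relative degeneracy guard: a numerically-constant series (e.g. the
    # clamped residual of self-orthogonalization) must not correlate its
    # own rounding noise
    if sa <= 1e-9 * (abs(a.mean()) + 1.0) or sb <= 1e-9 * (abs(b.mean()) + 1.0):
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def orth_pow_corr(c_i: np.ndarray, c_j: np.ndarray) -> float:
    """Orthogonalized log-power correlation, symmetrized over directions.

    Direction i->j correlates log|c_i|² with the log-power of c_j after
    projecting out its component in phase with c_i; identical signals have
    no orthogonal residual and return 0.
    """
    c_i, c_j = np.ravel(c_i), np.ravel(c_j)
    if c_i.size < 3:
        raise ValueError("need at least 3 samples")
    lp_i = np.log(np.maximum(np.abs(c_i) ** 2, _EPS))
    lp_j = np.log(np.maximum(np.abs(c_j) ** 2, _EPS))
    r_ij = _corr(lp_i, _log_orth_power(c_i, c_j))
    r_ji = _corr(lp_j, _log_orth_power(c_j, c_i))
    return 0.5 * (r_ij + r_ji)


def control_metrics(c_i: np.ndarray, c_j: np.ndarray) -> dict:
    """PowCorr, COH, iCOH and PLV for one pair of coefficient series."""
    c_i, c_j = np.ravel(c_i), np.ravel(c_j)
    p_i, p_j = np.abs(c_i) ** 2, np.abs(c_j) ** 2
    if p_i.mean() <= _EPS or p_j.mean() <= _EPS:
        raise ValueError("zero-power coefficient series")
    x = c_i * np.conj(c_j)
    coherency = np.mean(x) / np.sqrt(p_i.mean() * p_j.mean())
    u = x / np.maximum(np.abs(x), _EPS)
    return {
        "PowCorr": _corr(np.log(np.maximum(p_i, _EPS)),
                         np.log(np.maximum(p_j, _EPS))),
        "COH": float(abs(coherency)),
        "iCOH": float(np.imag(coherency)),
        "PLV": float(abs(np.mean(u))),
    }


def _pairwise_block(z: np.ndarray, epoch_slices: list,
                    n_epochs: int, n_reps: int,
                    rng: np.random.Generator,
                    metrics: tuple) -> dict:
    """All-metric link values for one frequency/condition.

    ``z``: (spaces, pooled samples) complex coefficients;
    ``epoch_slices``: per-epoch column slices of the pooled axis.
    """
    s, n = z.shape
    out = {}
    absz = np.maximum(np.abs(z), _EPS)
    logp = np.log(absz ** 2)

    if "PowCorr" in metrics:
        out["PowCorr"] = np.corrcoef(logp)
    if "COH" in metrics or "iCOH" in metrics:
        cross = (z @ z.conj().T) / n
        power = np.real(np.diag(cross))
        norm = np.sqrt(np.outer(power, power))
        coherency = cross / np.maximum(norm, _EPS)
        out["COH"] = np.abs(coherency)
        out["iCOH"] = np.imag(coherency)
    if "PLV" in metrics:
        zn = z / absz
        # X/|X| for pair (i,j) equals u_i conj(u_j): PLV from unit phasors
        out["PLV"] = np.abs((zn @ zn.conj().T) / n)

    if "orthPowCorr" in metrics:
        d = np.zeros((s, s))
        lc = logp - logp.mean(axis=1, keepdims=True)
        ls = np.maximum(logp.std(axis=1), _EPS)
        rms2 = np.mean(absz ** 2, axis=1)
        for i in range(s):
            im = np.imag(z * np.conj(z[i])[None, :]) / absz[i][None, :]
            floors = np.maximum((1e-10 * np.sqrt(rms2)) ** 2, _EPS)
            ly = np.log(np.maximum(im ** 2, floors[:, None]))
            lyc = ly - ly.mean(axis=1, keepdims=True)
            std_ly = ly.std(axis=1)
            lys = np.maximum(std_ly, _EPS)
            degenerate = std_ly <= 1e-9 * (np.abs(ly.mean(axis=1)) + 1.0)
            row = (lyc @ lc[i]) / n / (lys * ls[i])
            row[degenerate] = 0.0
            d[i] = row
        out["orthPowCorr"] = 0.5 * (d + d.T)

    if "wPLI" in metrics:
        n_avail = len(epoch_slices)
        sums = np.empty((n_avail, s, s))
        abs_sums = np.empty((n_avail, s, s))
        for e, sl in enumerate(epoch_slices):
            ze = z[:, sl]
            im = np.imag(ze[:, None, :] * np.conj(ze[None, :, :]))
            sums[e] = im.sum(axis=2)
            abs_sums[e] = np.abs(im).sum(axis=2)
        if n_avail < n_epochs:
            raise ValueError(
                f"only {n_avail} epochs available, {n_epochs} required "
                "for the subsampled wPLI estimator")
        acc = np.zeros((s, s))
        for _ in range(n_reps):
            pick = rng.choice(n_avail, size=n_epochs, replace=False)
            denom = abs_sums[pick].sum(axis=0)
            acc += np.abs(sums[pick].sum(axis=0)) / np.maximum(denom, _EPS)
        out["wPLI"] = acc / n_reps
    return out


def fc_tensor(wc: WaveletCoeffs, metrics: tuple = METRICS,
              conditions: tuple = ("EO", "EC"), n_epochs: int = 15,
              n_reps: int = 100, seed: int = 0) -> FCTensor:
    """Full connectivity tensor over links x frequencies x conditions.

    Epoch x window samples are pooled within each condition for all
    metrics except wPLI, which uses the epoch-level subsampling estimator
    (``n_epochs`` epochs per draw, ``n_reps`` draws).
    """
    n_space = len(wc.channels) if wc.channels else wc.coeffs[0].shape[1]
    iu = np.triu_indices(n_space, k=1)
    links = np.stack(iu, axis=1)
    values = np.full((len(links), len(wc.freqs), len(conditions),
                      len(metrics)), np.nan)
    rng = np.random.default_rng(seed)
    for ci, cond in enumerate(conditions):
        sel = np.where(wc.condition == cond)[0]
        if sel.size == 0:
            raise ValueError(f"no epochs with condition {cond}")
        for fi in range(len(wc.freqs)):
            c = wc.coeffs[fi][sel]                    # epochs x space x win
            n_e, _, n_w = c.shape
            z = np.moveaxis(c, 1, 0).reshape(n_space, n_e * n_w)
            slices = [slice(e * n_w, (e + 1) * n_w) for e in range(n_e)]
            block = _pairwise_block(z, slices, n_epochs, n_reps, rng,
                                    tuple(metrics))
            for mi, m in enumerate(metrics):
                values[:, fi, ci, mi] = block[m][iu]
    return FCTensor(values=values, links=links, freqs=wc.freqs.copy(),
                    conditions=tuple(conditions), metrics=tuple(metrics),
                    channels=list(wc.channels))
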