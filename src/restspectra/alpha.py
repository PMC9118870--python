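"""Alpha-peak detection and the three summary alpha measures.

A Gaussian peak over a power-law background is fitted to the occipital
eyes-closed spectrum; the peak frequency f_p (bounded to [6, 13] Hz), the
absolute alpha-band power in [f_p - 2, f_p + 2] Hz for each condition, and
the reactivity to eye opening R = 1 - P_EO / P_EC summarise the subject's
alpha rhythm. A single f_p per subject (from the eyes-closed fit) is used
for both conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .data import OCCIPITAL
from .spectral import PSD

__all__ = ["AlphaFit", "AlphaSummary", "fit_alpha_peak", "alpha_band_power",
           "reactivity", "alpha_summary"]


@dataclass
class AlphaFit:
    f_p: float
    gauss_amp: float
    gauss_sigma: float
    powerlaw_a: float
    powerlaw_b: float
    converged: bool
    has_peak: bool


@dataclass
class AlphaSummary:
    f_p: float
    p_eo: float
    p_ec: float
    r: float


def _model(f, a, b, amp, f_p, sigma):
    return a * f ** (-b) + amp * np.exp(-((f - f_p) ** 2) / (2.0 * sigma ** 2))


def fit_alpha_peak(psd_ec: PSD, occipital: Sequence[str] = OCCIPITAL,
                   fit_range: tuple = (2.0, 20.0),
                   prominence: float = 0.10) -> AlphaFit:
    """Fit ``a f^-b + A exp(-(f - f_p)^2 / 2 sigma^2)`` to the occipital EC
    spectrum.

    The fit minimises squared error on log-power over ``fit_range``, which
    equalises the dynamic range of 1/f backgrounds; f_p is bounded to
    [6, 13] Hz. ``has_peak`` requires convergence, a positive Gaussian
    amplitude and a peak at least ``prominence`` of the background level
    at f_p — subjects without a clear peak are flagged for exclusion.
    """
    idx = [psd_ec.channels.index(c) for c in occipital
           if c in psd_ec.channels]
    if not idx:
        raise ValueError("no occipital channels present in the PSD")
    sel = (psd_ec.freqs >= fit_range[0]) & (psd_ec.freqs <= fit_range[1])
    f = psd_ec.freqs[sel]
    if f.size < 6:
        raise ValueError("PSD must cover the [2, 20] Hz fit range")
    p = psd_ec.power[idx][:, sel].mean(axis=0)
    p = np.maximum(p, 1e-30)
    logp = np.log(p)

    def resid(theta):
        a, b, amp, f_p, sigma = theta
        return np.log(np.maximum(_model(f, a, b, amp, f_p, sigma), 1e-30)) - logp

    # moment-based start: background from the edges, peak at the maximum
    # of the background-detrended spectrum inside [6, 13]
    b0 = 1.0
    a0 = float(np.exp(np.median(logp + b0 * np.log(f))))
    band = (f >= 6.0) & (f <= 13.0)
    detrended = p - a0 * f ** (-b0)
    if band.any() and np.nanmax(detrended[band]) > 0:
        f_p0 = float(f[band][np.nanargmax(detrended[band])])
        amp0 = float(max(np.nanmax(detrended[band]), 1e-6))
    else:
        f_p0, amp0 = 10.0, float(max(p.max() * 0.1, 1e-6))
    x0 = [a0, b0, amp0, f_p0, 1.0]
    lower = [1e-12, 0.0, 0.0, 6.0, 0.3]
    upper = [np.inf, 5.0, np.inf, 13.0, 5.0]
    try:
        sol = least_squares(resid, x0, bounds=(lower, upper), max_nfev=2000)
        converged = bool(sol.success)
        a, b, amp, f_p, sigma = sol.x
    except Exception:
        converged, (a, b, amp, f_p, sigma) = False, x0
    background_at_peak = a * f_p ** (-b)
    # a fit pinned to the search boundary means the true peak lies outside
    # the alpha range: no clear alpha peak
    interior = 6.0 + 0.1 < f_p < 13.0 - 0.1
    has_peak = (converged and amp > 0
                and amp >= prominence * background_at_peak
                and interior)
    return AlphaFit(f_p=float(f_p), gauss_amp=float(amp),
                    gauss_sigma=float(sigma), powerlaw_a=float(a),
                    powerlaw_b=float(b), converged=converged,
                    has_peak=bool(has_peak))


def alpha_band_power(psd: PSD, f_p: float,
                     occipital: Sequence[str] = OCCIPITAL) -> float:
    """Absolute power in [f_p - 2, f_p + 2] Hz averaged over occipital
    channels (trapezoidal integration of the PSD, µV²)."""
    missing = [c for c in occipital if c not in psd.channels]
    if missing:
        raise KeyError(f"occipital channels missing from PSD: {missing}")
    lo, hi = f_p - 2.0, f_p + 2.0
    if lo < psd.freqs[0] - 1e-9 or hi > psd.freqs[-1] + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] Hz outside the PSD range")
    idx = [psd.channels.index(c) for c in occipital]
    sel = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
    return float(np.trapezoid(psd.power[idx][:, sel].mean(axis=0),
                              psd.freqs[sel]))


def reactivity(p_eo: float, p_ec: float) -> float:
    """Reactivity to eye opening, R = 1 - P_EO / P_EC (<= 1; negative if
    alpha power rises with open eyes)."""
    if p_ec <= 0:
        raise ValueError("eyes-closed power must be positive")
    return 1.0 - p_eo / p_ec


def alpha_summary(psd_eo: PSD, psd_ec: PSD,
                  occipital: Sequence[str] = OCCIPITAL,
                  f_p_override: float | None = None) -> AlphaSummary | None:
    """Full per-subject summary; returns None when no clear peak is found.

    ``f_p_override`` replaces the automatic fit (the equivalent of a
    manually refined peak frequency).
    """
    if f_p_override is None:
        fit = fit_alpha_peak(psd_ec, occipital)
        if not fit.has_peak:
            return None
        f_p = fit.f_p
    else:
        f_p = float(f_p_override)
    p_eo = alpha_band_power(psd_eo, f_p, occipital)
    p_ec = alpha_band_power(psd_ec, f_p, occipital)
    return AlphaSummary(f_p=f_p, p_eo=p_eo, p_ec=p_ec,
                        r=reactivity(p_eo, p_ec))
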