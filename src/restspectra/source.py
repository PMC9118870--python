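"""LCMV beamformer projection, ROI definition and ROI time series.

The forward model is consumed, never constructed: a :class:`Leadfield`
holds the sensor gain of a unit dipole at each source position for three
orthogonal orientations. Source time series come from a linearly
constrained minimum-variance (LCMV) beamformer with diagonal loading and
max-power orientation selection; sources are grouped into mirror-symmetric
ROIs by k-means and each ROI is summarised by the first principal
component of its member time series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

__all__ = ["Leadfield", "ROIPartition", "skull_conductivity", "lcmv_filters",
           "apply_filters", "make_rois", "roi_timeseries"]


@dataclass
class Leadfield:
    """Gain matrix (sensors x sources x 3 orientations) and source positions (mm)."""

    gain: np.ndarray
    positions: np.ndarray
    spacing: float = 15.0  # grid spacing in mm, used for source adjacency

    def __post_init__(self) -> None:
        self.gain = np.asarray(self.gain, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.gain.ndim != 3 or self.gain.shape[2] != 3:
            raise ValueError("gain must be sensors x sources x 3")
        if len(self.positions) != self.gain.shape[1]:
            raise ValueError("positions must match the number of sources")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("gain contains non-finite values")

    @property
    def n_sources(self) -> int:
        return self.gain.shape[1]

    @property
    def n_sensors(self) -> int:
        return self.gain.shape[0]


@dataclass
class ROIPartition:
    """Assignment of every source to one ROI, with ROI adjacency."""

    labels: np.ndarray        # per-source ROI id, 0..n_rois-1
    centroids: np.ndarray     # n_rois x 3
    adjacency: np.ndarray     # n_rois x n_rois boolean, symmetric, irreflexive

    @property
    def n_rois(self) -> int:
        return len(self.centroids)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_rois)


def skull_conductivity(age: float) -> float:
    """Age-dependent skull conductivity in mS/m.

    Decays from ~66.7 mS/m at birth towards an adult asymptote of
    3.958 mS/m: ``3.958 + 62.77 exp(-0.2404 age)``.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    return 3.958 + 62.77 * np.exp(-0.2404 * age)


def lcmv_filters(cov: np.ndarray, lf: Leadfield,
                 reg_frac: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Unit-gain LCMV spatial filters with max-power orientation.

    The sensor covariance is regularized by diagonal loading with
    ``reg_frac`` of its average trace. Per source the three-orientation
    filter is ``W = C_r^-1 L (L' C_r^-1 L)^-1``; the retained orientation
    is the dominant eigenvector of the 3x3 source output-power matrix
    ``(L' C_r^-1 L)^-1``, and the final one-dimensional filter satisfies
    ``w' L theta = 1``.

    Returns ``(filters, orientations)`` with shapes (sources x sensors)
    and (sources x 3).
    """
    cov = np.asarray(cov, dtype=float)
    n = cov.shape[0]
    if cov.shape != (n, n) or n != lf.n_sensors:
        raise ValueError("covariance must be n_sensors x n_sensors")
    if not np.allclose(cov, cov.T, atol=1e-8 * max(1.0, np.abs(cov).max())):
        raise ValueError("covariance must be symmetric")
    c_r = cov + reg_frac * (np.trace(cov) / n) * np.eye(n)
    c_inv = np.linalg.inv(c_r)

    filters = np.empty((lf.n_sources, n))
    orients = np.empty((lf.n_sources, 3))
    for s in range(lf.n_sources):
        L = lf.gain[:, s, :]                       # sensors x 3
        gram = L.T @ c_inv @ L
        try:
            gram_inv = np.linalg.inv(gram)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular L' C^-1 L for source {s}") from err
        # output power of the unit-gain vector beamformer is gram_inv;
        # max-power orientation = its dominant eigenvector
        w_eval, w_evec = eigh(gram_inv)
        theta = w_evec[:, -1]
        l_theta = L @ theta                        # sensors
        denom = float(l_theta @ c_inv @ l_theta)
        w = (c_inv @ l_theta) / denom
        filters[s] = w
        orients[s] = theta
    return filters, orients


def apply_filters(filters: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Project sensor data (... x sensors x samples) to source space."""
    return np.einsum("ks,...st->...kt", filters, data)


def make_rois(positions: np.ndarray, k_per_hemisphere: int = 25,
              seed: int = 0, spacing: float = 15.0) -> ROIPartition:
    """Mirror-symmetric ROI partition via k-means on one hemisphere.

    Clustering runs on folded coordinates (|x|, y, z); each cluster yields
    a right- and a left-hemisphere ROI (midline sources join the right
    one). ROIs are adjacent iff some cross pair of their sources lies
    within the 26-neighbourhood of the grid (distance <= 1.5 x spacing).
    """
    positions = np.asarray(positions, dtype=float)
    folded = positions.copy()
    folded[:, 0] = np.abs(folded[:, 0])
    last_err: Exception | None = None
    for attempt in range(10):
        km = KMeans(n_clusters=k_per_hemisphere, n_init=10,
                    random_state=seed + attempt)
        half_labels = km.fit_predict(folded)
        labels = np.where(positions[:, 0] > 0, half_labels,
                          half_labels + k_per_hemisphere)
        # midline sources balance the two mirror ROIs of their cluster
        counts = np.bincount(labels[positions[:, 0] != 0],
                             minlength=2 * k_per_hemisphere)
        for i in np.where(positions[:, 0] == 0)[0]:
            right, left = half_labels[i], half_labels[i] + k_per_hemisphere
            tgt = right if counts[right] <= counts[left] else left
            labels[i] = tgt
            counts[tgt] += 1
        sizes = np.bincount(labels, minlength=2 * k_per_hemisphere)
        if np.all(sizes > 0):
            break
        last_err = ValueError("empty ROI after k-means convergence")
    else:
        raise last_err  # pragma: no cover - 10 reseeds failing is pathological
    n_rois = 2 * k_per_hemisphere
    centroids = np.stack([positions[labels == r].mean(axis=0)
                          for r in range(n_rois)])

    thresh = 1.5 * spacing + 1e-6
    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=2)
    src_adj = (dist <= thresh) & (dist > 1e-9)
    adjacency = np.zeros((n_rois, n_rois), dtype=bool)
    for a in range(n_rois):
        in_a = labels == a
        for b in range(a + 1, n_rois):
            if src_adj[np.ix_(in_a, labels == b)].any():
                adjacency[a, b] = adjacency[b, a] = True
    return ROIPartition(labels=labels, centroids=centroids, adjacency=adjacency)


def roi_timeseries(source_ts: np.ndarray, part: ROIPartition) -> np.ndarray:
    """First-PC summary series per ROI (rois x time).

    The component sign is fixed so that it correlates positively with the
    mean of the member series, making results reproducible across runs.
    """
    source_ts = np.asarray(source_ts, dtype=float)
    out = np.empty((part.n_rois, source_ts.shape[1]))
    for r in range(part.n_rois):
        members = source_ts[part.labels == r]
        if members.shape[0] == 0:
            raise ValueError(f"ROI {r} has no member sources")
        centered = members - members.mean(axis=1, keepdims=True)
        if members.shape[0] == 1:
            out[r] = centered[0]
            continue
        # first left singular vector of the member x time matrix
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        pc = s[0] * vt[0]
        mean_series = centered.mean(axis=0)
        if np.dot(pc, mean_series) < 0:
            pc = -pc
        out[r] = pc
    return out
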