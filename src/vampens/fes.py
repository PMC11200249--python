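"""Free-energy landscapes on time-lagged independent components.

tICA finds the linear projections of the features with the slowest
autocorrelation at a lag tau, by solving the symmetrized generalized
eigenproblem  C(tau) v = lambda C(0) v  on mean-free data.  Frames projected
on the two leading components give a 2-D map; Gaussian kernel density
estimation on a random subsample (default 10% of the frames) yields a
density p-hat, and the free-energy surface is F = -ln p-hat in kT units,
shifted so its minimum is zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.stats import gaussian_kde

from .features import TrajectoryDataset

__all__ = ["TicaProjection", "FreeEnergySurface", "fit_tica", "estimate_fes"]


@dataclass
class TicaProjection:
    """Two leading tICA coordinates per frame plus the reusable transform."""

    components: np.ndarray      # (n_frames, 2)
    eigenvalues: np.ndarray     # descending
    lag_steps: int
    mean: np.ndarray
    projection: np.ndarray      # (F, 2)

    def transform(self, frames: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(frames) - self.mean) @ self.projection


def fit_tica(dataset: TrajectoryDataset, lag_steps: int, n_components: int = 2,
             eps: float = 1e-10) -> TicaProjection:
    """Fit tICA with the symmetrized (reversible) covariance estimator."""
    if lag_steps < 1:
        raise ValueError("lag_steps must be >= 1")
    x0s = [t[:-lag_steps] for t in dataset.trajectories if t.shape[0] > lag_steps]
    x1s = [t[lag_steps:] for t in dataset.trajectories if t.shape[0] > lag_steps]
    if not x0s:
        raise ValueError(f"no trajectory is longer than the lag ({lag_steps} steps)")
    x0 = np.concatenate(x0s)
    x1 = np.concatenate(x1s)
    mean = 0.5 * (x0.mean(axis=0) + x1.mean(axis=0))
    a = x0 - mean
    b = x1 - mean
    p = a.shape[0]
    c0 = (a.T @ a + b.T @ b) / (2 * p)
    ct = (a.T @ b + b.T @ a) / (2 * p)
    # regularize near-singular instantaneous covariance
    smallest = np.linalg.eigvalsh(c0)[0]
    if smallest < eps * np.trace(c0) / c0.shape[0]:
        warnings.warn("instantaneous covariance is rank-deficient; regularizing")
        c0 = c0 + eps * np.trace(c0) / c0.shape[0] * np.eye(c0.shape[0])
    vals, vecs = eigh(ct, c0)
    order = np.argsort(vals)[::-1][:n_components]
    eigenvalues = vals[order]
    projection = vecs[:, order]
    frames = dataset.concatenated()
    return TicaProjection(
        components=(frames - mean) @ projection,
        eigenvalues=eigenvalues,
        lag_steps=lag_steps,
        mean=mean,
        projection=projection,
    )


@dataclass
class FreeEnergySurface:
    """-ln density on a regular 2-D grid, in kT, minimum shifted to 0."""

    grid: np.ndarray            # (ny, nx) free energies
    x_edges: np.ndarray
    y_edges: np.ndarray
    bandwidth: float
    subsample_fraction: float

    def minimum_locations(self) -> np.ndarray:
        """Grid indices of strict local minima (4-neighbourhood)."""
        g = self.grid
        mins = []
        for i in range(1, g.shape[0] - 1):
            for j in range(1, g.shape[1] - 1):
                v = g[i, j]
                if v < g[i - 1, j] and v < g[i + 1, j] and \
                   v < g[i, j - 1] and v < g[i, j + 1]:
                    mins.append((i, j))
        return np.asarray(mins, dtype=np.int64).reshape(-1, 2)


def estimate_fes(projection: TicaProjection, subsample_fraction: float = 0.1,
                 seed: int = 0, grid_size: int = 100,
                 bandwidth_scale: float = 1.0, pad: float = 0.05) -> FreeEnergySurface:
    """Gaussian-KDE free-energy surface on a subsample of the projected frames.

    Bandwidth is Scott's rule times ``bandwidth_scale``; the grid covers the
    data extent padded by ``pad`` on each side.
    """
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must be in (0, 1]")
    pts = projection.components
    n = pts.shape[0]
    k = max(int(round(subsample_fraction * n)), 0)
    if k < 100:
        raise ValueError(
            f"subsample of {k} points is too small for a density estimate (need >= 100)"
        )
    idx = np.random.default_rng(seed).choice(n, size=k, replace=False)
    sample = pts[idx]
    kde = gaussian_kde(sample.T, bw_method=sample.shape[0] ** (-1.0 / 6) * bandwidth_scale)
    lo = sample.min(axis=0)
    hi = sample.max(axis=0)
    span = hi - lo
    lo -= pad * span
    hi += pad * span
    xe = np.linspace(lo[0], hi[0], grid_size)
    ye = np.linspace(lo[1], hi[1], grid_size)
    gx, gy = np.meshgrid(xe, ye)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()])).reshape(grid_size, grid_size)
    with np.errstate(divide="ignore"):
        f = -np.log(dens)
    f -= np.nanmin(f[np.isfinite(f)])
    return FreeEnergySurface(
        grid=f, x_edges=xe, y_edges=ye,
        bandwidth=float(kde.factor), subsample_fraction=subsample_fraction,
    )
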