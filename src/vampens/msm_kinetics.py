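"""Koopman/transition-matrix estimation and kinetic read-outs.

The trained state-assignment function chi turns trajectories into soft state
counts: with X = chi(frames at t) and Y = chi(frames at t + tau), the matrix
C = X^T Y collects probability-weighted transition counts and C00 = X^T X
the instantaneous weights.  The (constrained) row-stochastic transition
matrix T(tau) estimated from these counts yields the usual MSM quantities:

* equilibrium distribution pi (stationary left eigenvector),
* mean first-passage times of the tau-jump chain, scaled to physical time,
* implied timescales t_i = -tau / ln |lambda_i|,
* Chapman-Kolmogorov validation T(tau)^k vs directly estimated T(k tau).

Reversibility and non-negativity ("physical constraints") are imposed at
this estimation step by the standard self-consistent reweighting iteration
for the reversible maximum-likelihood transition matrix, which by
construction satisfies detailed balance pi_i T_ij = pi_j T_ji with
non-negative entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eig

from .features import TrajectoryDataset
from .vampnet import FramePairSet, SoftModel, make_frame_pairs

__all__ = [
    "KoopmanEstimate",
    "KineticsSummary",
    "estimate_koopman",
    "equilibrium_distribution",
    "mean_first_passage_times",
    "implied_timescales",
    "chapman_kolmogorov",
    "median_centered_band",
    "ensemble_kinetics",
]


@dataclass
class KoopmanEstimate:
    """Row-stochastic transition matrix at one lag with its stationary vector."""

    transition_matrix: np.ndarray
    stationary: np.ndarray
    lag_time: float
    constraint_mode: str = "reversible-nonnegative"


def _soft_counts(model: SoftModel, pairs: FramePairSet) -> np.ndarray:
    x = model.predict(pairs.x0)
    y = model.predict(pairs.x1)
    c = x.T @ y
    mass = x.sum(axis=0)
    dead = np.nonzero(mass < 1e-6 * len(pairs))[0]
    if dead.size:
        raise ValueError(
            f"state(s) {[int(d) + 1 for d in dead]} carry negligible probability "
            "mass on the given pairs; the chain is effectively reducible"
        )
    return c


def _reversible_mle(counts: np.ndarray, tol: float = 1e-12,
                    max_iter: int = 10_000) -> tuple[np.ndarray, np.ndarray]:
    """Reversible maximum-likelihood transition matrix from a count matrix.

    Self-consistent fixed point over the symmetric flux variables
    x_ij <- (c_ij + c_ji) / (c_i / x_i. + c_j / x_j.); T_ij = x_ij / x_i..
    Detailed balance holds exactly at the fixed point because x is symmetric.
    """
    c = np.asarray(counts, dtype=np.float64)
    csym = c + c.T
    crow = c.sum(axis=1)
    x = csym / csym.sum()
    for _ in range(max_iter):
        xrow = x.sum(axis=1)
        denom = (crow / xrow)[:, None] + (crow / xrow)[None, :]
        x_new = csym / denom
        x_new /= x_new.sum()
        delta = np.abs(x_new - x).max()
        x = x_new
        if delta < tol:
            break
    xrow = x.sum(axis=1)
    t = x / xrow[:, None]
    pi = xrow / xrow.sum()
    return t, pi


def estimate_koopman(model: SoftModel, pairs: FramePairSet,
                     constraint_mode: str = "reversible-nonnegative",
                     lag_time: float | None = None) -> KoopmanEstimate:
    """Estimate T(tau) from the model's soft state probabilities over pairs.

    ``constraint_mode="reversible-nonnegative"`` (default) returns the
    reversible MLE; ``"unconstrained"`` row-normalizes the soft counts.
    """
    counts = _soft_counts(model, pairs)
    if constraint_mode == "reversible-nonnegative":
        t, pi = _reversible_mle(counts)
    elif constraint_mode == "unconstrained":
        t = counts / counts.sum(axis=1, keepdims=True)
        pi = equilibrium_distribution(t)
    else:
        raise ValueError(f"unknown constraint_mode {constraint_mode!r}")
    if lag_time is None:
        lag_time = float(pairs.lag_steps)
    return KoopmanEstimate(t, pi, lag_time, constraint_mode)


def equilibrium_distribution(transition_matrix: np.ndarray,
                             tol: float = 1e-8) -> np.ndarray:
    """Stationary left eigenvector of a row-stochastic irreducible matrix."""
    t = np.asarray(transition_matrix, dtype=np.float64)
    if not np.allclose(t.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("matrix is not row-stochastic")
    vals, vecs = eig(t.T)
    idx = int(np.argmax(vals.real))
    if abs(vals[idx].imag) > tol:
        raise ValueError("dominant eigenvalue has a non-negligible imaginary part")
    if abs(vals[idx].real - 1.0) > 1e-6:
        raise ValueError("no unit eigenvalue found; matrix may be sub-stochastic")
    pi = vecs[:, idx].real
    pi = np.abs(pi)
    if pi.min() < tol * pi.max():
        raise ValueError("stationary vector has (near-)zero entries; chain is reducible")
    return pi / pi.sum()


def mean_first_passage_times(transition_matrix: np.ndarray,
                             lag_time: float = 1.0) -> np.ndarray:
    """MFPT matrix of the tau-jump chain in physical units; diagonal is 0.

    mfpt[i, j] solves (I - T_{-j}) h = 1 over the states without j, scaled
    by the lag time.
    """
    t = np.asarray(transition_matrix, dtype=np.float64)
    m = t.shape[0]
    mfpt = np.zeros((m, m))
    for j in range(m):
        keep = [i for i in range(m) if i != j]
        sub = t[np.ix_(keep, keep)]
        try:
            h = np.linalg.solve(np.eye(m - 1) - sub, np.ones(m - 1))
        except np.linalg.LinAlgError as err:
            raise ValueError(f"chain is reducible with respect to state {j + 1}") from err
        mfpt[keep, j] = h * lag_time
    return mfpt


def implied_timescales(transition_matrix: np.ndarray, lag_time: float) -> np.ndarray:
    """t_i = -tau / ln |lambda_i| for the non-unit eigenvalues, sorted descending.

    Non-positive eigenvalues (possible in noisy reversible estimates) yield
    NaN entries rather than an error.
    """
    vals = np.linalg.eigvals(np.asarray(transition_matrix, dtype=np.float64))
    vals = vals[np.argsort(-np.abs(vals))][1:]  # drop the stationary eigenvalue
    out = np.full(len(vals), np.nan)
    for i, lam in enumerate(vals):
        if abs(lam.imag) < 1e-12 and lam.real <= 0:
            continue  # flagged: no timescale for a non-positive real eigenvalue
        mag = abs(lam)
        if 0 < mag < 1:
            out[i] = -lag_time / np.log(mag)
    return out


def implied_timescales_table(models_by_lag: dict[int, list[SoftModel]],
                             pairs_by_lag: dict[int, FramePairSet],
                             frame_interval: float = 1.0) -> dict[int, np.ndarray]:
    """Implied timescales per lag, stacked over the models given for that lag.

    Returns {lag_steps: (n_models, M-1) array} in physical units.  Requires
    at least two lags, since the point of the table is the flatness check.
    """
    if len(models_by_lag) < 2:
        raise ValueError("need at least two lags for an implied-timescale table")
    table = {}
    for lag, models in models_by_lag.items():
        rows = []
        for model in models:
            est = estimate_koopman(model, pairs_by_lag[lag],
                                   lag_time=lag * frame_interval)
            rows.append(implied_timescales(est.transition_matrix, est.lag_time))
        table[lag] = np.vstack(rows)
    return table


def chapman_kolmogorov(model: SoftModel, dataset: TrajectoryDataset,
                       k_max: int = 5,
                       constraint_mode: str = "reversible-nonnegative"):
    """Chapman-Kolmogorov test: T(tau)^k versus directly estimated T(k tau).

    Returns (ks, predicted, estimated, discrepancy) where predicted[k-1] and
    estimated[k-1] are M x M matrices and discrepancy the max-abs difference.
    Lags k*tau that no trajectory supports are truncated with a warning.
    """
    import warnings

    tau = model.lag_steps
    base = estimate_koopman(model, make_frame_pairs(dataset, tau),
                            constraint_mode=constraint_mode)
    ks, predicted, estimated, discrepancy = [], [], [], []
    for k in range(1, k_max + 1):
        try:
            pairs_k = make_frame_pairs(dataset, k * tau)
        except ValueError:
            warnings.warn(f"no pairs at lag {k * tau}; CK test truncated at k={k - 1}")
            break
        est_k = estimate_koopman(model, pairs_k, constraint_mode=constraint_mode)
        pred = np.linalg.matrix_power(base.transition_matrix, k)
        ks.append(k)
        predicted.append(pred)
        estimated.append(est_k.transition_matrix)
        discrepancy.append(float(np.abs(pred - est_k.transition_matrix).max()))
    return ks, predicted, estimated, discrepancy


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------

def median_centered_band(values: np.ndarray, coverage: float = 0.95,
                         axis: int = 0):
    """Median and the band of half-width = coverage-percentile of |v - median|.

    The convention for ensemble error bars: the interval centered on the
    median containing ``coverage`` of the per-model values (linear percentile
    interpolation).
    """
    values = np.asarray(values, dtype=np.float64)
    med = np.median(values, axis=axis)
    half = np.percentile(np.abs(values - np.expand_dims(med, axis)),
                         100.0 * coverage, axis=axis)
    return med, med - half, med + half


@dataclass
class KineticsSummary:
    """Per-ensemble kinetic read-outs with median-centered percentile bands."""

    stationary_median: np.ndarray
    stationary_lo: np.ndarray
    stationary_hi: np.ndarray
    mfpt_median: np.ndarray
    timescales_median: np.ndarray
    timescales_lo: np.ndarray
    timescales_hi: np.ndarray
    lag_time: float
    per_model_stationary: np.ndarray
    per_model_timescales: np.ndarray

    def to_dict(self) -> dict:
        return {
            "lag_time": self.lag_time,
            "stationary_median": self.stationary_median.tolist(),
            "stationary_band": [self.stationary_lo.tolist(), self.stationary_hi.tolist()],
            "mfpt_median": self.mfpt_median.tolist(),
            "timescales_median": self.timescales_median.tolist(),
            "timescales_band": [self.timescales_lo.tolist(), self.timescales_hi.tolist()],
        }


def ensemble_kinetics(ensemble, dataset: TrajectoryDataset,
                      constraint_mode: str = "reversible-nonnegative",
                      coverage: float = 0.95) -> KineticsSummary:
    """Kinetics over all ensemble members, permutation-corrected and summarized."""
    pairs = make_frame_pairs(dataset, ensemble.lag_steps)
    lag_time = ensemble.lag_steps * dataset.frame_interval
    pis, mfpts, timescales = [], [], []
    for n, model in enumerate(ensemble.models):
        est = estimate_koopman(model, pairs, constraint_mode=constraint_mode,
                               lag_time=lag_time)
        perm = ensemble.state_permutations[n] if ensemble.aligned else np.arange(ensemble.n_states)
        t_aligned = np.empty_like(est.transition_matrix)
        t_aligned[np.ix_(perm, perm)] = est.transition_matrix
        pi_aligned = np.empty_like(est.stationary)
        pi_aligned[perm] = est.stationary
        pis.append(pi_aligned)
        mfpts.append(mean_first_passage_times(t_aligned, lag_time))
        timescales.append(implied_timescales(t_aligned, lag_time))
    pis = np.array(pis)
    timescales = np.array(timescales)
    pi_med, pi_lo, pi_hi = median_centered_band(pis, coverage)
    ts_med, ts_lo, ts_hi = median_centered_band(timescales, coverage)
    return KineticsSummary(
        stationary_median=pi_med, stationary_lo=pi_lo, stationary_hi=pi_hi,
        mfpt_median=np.median(np.array(mfpts), axis=0),
        timescales_median=ts_med, timescales_lo=ts_lo, timescales_hi=ts_hi,
        lag_time=lag_time,
        per_model_stationary=pis,
        per_model_timescales=timescales,
    )
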