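"""Gradient-based characterization of learned states.

For a state m, the saliency vector g_m is the ensemble average of the exact
gradient of the state's output probability with respect to the raw input
features (inter-residue distances, Angstrom), chain-ruled through each
model's input standardizer:

    g_m = (1 / N) sum_n  d chi_nm / d xi,

averaged further over a random sample of frames (default 10,000).  The sign
convention is fixed: a positive entry means the state's probability
increases when that inter-residue distance increases.  For visualization,
g_m is arranged back into the R x R matrix form of the distance matrix, and
can be aggregated per residue (signed or absolute sums over all pairs a
residue participates in).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import TrajectoryDataset, devectorize, pair_index
from .vampnet import ModelEnsemble, SoftModel, hard_assign

__all__ = [
    "GradientMap",
    "frame_gradient",
    "ensemble_gradient",
    "state_conditioned_gradient",
    "aggregate_by_residue",
    "plot_gradient_map",
]

SIGN_CONVENTION = "positive => probability increases when the distance increases"


@dataclass
class GradientMap:
    """Ensemble-averaged saliency of one state."""

    g: np.ndarray                   # (F,), per raw-feature gradient, 1/Angstrom
    matrix_form: np.ndarray         # (R, R), excluded bands NaN
    state: int
    n_frames_averaged: int
    per_residue_signed: np.ndarray
    per_residue_abs: np.ndarray
    sign_convention: str = SIGN_CONVENTION

    @property
    def n_residues(self) -> int:
        return self.matrix_form.shape[0]


def frame_gradient(model: SoftModel, frames: np.ndarray, state: int) -> np.ndarray:
    """Exact d p_state / d (raw features) for one frame or a batch.

    The network sees standardized inputs, so the network gradient is divided
    by the per-feature scale to land in physical units (per Angstrom).
    """
    if not 0 <= state < model.n_states:
        raise ValueError(f"state {state} out of range 0..{model.n_states - 1}")
    frames = np.asarray(frames, dtype=np.float64)
    single = frames.ndim == 1
    x = model.standardizer.transform(np.atleast_2d(frames))
    dx = model.net.grad_output_wrt_input(x, state) / model.standardizer.scale
    if not np.all(np.isfinite(dx)):
        bad = np.nonzero(~np.isfinite(dx).all(axis=1))[0]
        raise FloatingPointError(f"non-finite gradient for frame(s) {bad.tolist()}")
    return dx[0] if single else dx


def _build_map(g: np.ndarray, state: int, n_frames: int,
               n_residues: int) -> GradientMap:
    matrix = devectorize(g, n_residues)
    return GradientMap(
        g=g,
        matrix_form=matrix,
        state=state,
        n_frames_averaged=n_frames,
        per_residue_signed=_aggregate(g, n_residues, signed=True),
        per_residue_abs=_aggregate(g, n_residues, signed=False),
    )


def _sample_frames(frames: np.ndarray, n_frames: int, seed: int) -> np.ndarray:
    import warnings

    total = frames.shape[0]
    if total <= n_frames:
        if total < n_frames:
            warnings.warn(
                f"dataset has only {total} frames; using all instead of {n_frames}"
            )
        return frames
    idx = np.random.default_rng(seed).choice(total, size=n_frames, replace=False)
    return frames[idx]


def ensemble_gradient(ensemble: ModelEnsemble, dataset: TrajectoryDataset,
                      state: int, n_frames: int = 10_000, seed: int = 0,
                      frames: np.ndarray | None = None) -> GradientMap:
    """Saliency map of a common state, averaged over models and sampled frames.

    Frames are sampled uniformly without replacement; each model contributes
    the gradient of its *own* output node carrying the common state label
    (permutation-corrected).
    """
    if not ensemble.aligned:
        raise RuntimeError("ensemble is not aligned; run align_within_system first")
    if frames is None:
        frames = dataset.concatenated()
    sample = _sample_frames(np.asarray(frames, dtype=np.float64), n_frames, seed)
    acc = np.zeros(sample.shape[1])
    for n, model in enumerate(ensemble.models):
        own_state = ensemble.model_state_for(n, state)
        acc += frame_gradient(model, sample, own_state).mean(axis=0)
    g = acc / ensemble.n_models
    return _build_map(g, state, sample.shape[0], dataset.n_residues)


def state_conditioned_gradient(ensemble: ModelEnsemble, dataset: TrajectoryDataset,
                               state: int, condition_state: int,
                               n_frames: int = 10_000, seed: int = 0) -> GradientMap:
    """As :func:`ensemble_gradient`, sampling only frames hard-assigned to
    ``condition_state``."""
    import warnings

    if not 0 <= condition_state < ensemble.n_states:
        raise ValueError(f"condition_state {condition_state} out of range")
    frames = dataset.concatenated()
    labels = hard_assign(ensemble, frames)
    pool = frames[labels == condition_state]
    if pool.shape[0] == 0:
        raise ValueError(f"no frames are hard-assigned to state {condition_state}")
    if pool.shape[0] < 100:
        warnings.warn(
            f"only {pool.shape[0]} frames hard-assigned to state {condition_state}; "
            "proceeding with all of them"
        )
    return ensemble_gradient(ensemble, dataset, state, n_frames, seed, frames=pool)


def _aggregate(g: np.ndarray, n_residues: int, signed: bool) -> np.ndarray:
    pairs = pair_index(n_residues)
    vals = g if signed else np.abs(g)
    out = np.zeros(n_residues)
    np.add.at(out, pairs[:, 0], vals)
    np.add.at(out, pairs[:, 1], vals)
    return out


def aggregate_by_residue(gmap: GradientMap, mode: str = "abs-sum") -> np.ndarray:
    """Per-residue profile: sum over all kept pairs the residue participates in.

    ``mode="signed-sum"`` keeps signs (cancellation possible);
    ``mode="abs-sum"`` (default) is the importance profile.
    """
    if mode == "signed-sum":
        return _aggregate(gmap.g, gmap.n_residues, signed=True)
    if mode == "abs-sum":
        return _aggregate(gmap.g, gmap.n_residues, signed=False)
    raise ValueError(f"mode must be 'signed-sum' or 'abs-sum', got {mode!r}")


def plot_gradient_map(gmap: GradientMap, ax=None, percentile: float = 99.0):
    """Diverging heatmap of the matrix form; excluded bands stay neutral."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    finite = gmap.matrix_form[np.isfinite(gmap.matrix_form)]
    vmax = np.percentile(np.abs(finite), percentile) if finite.size else 1.0
    vmax = vmax if vmax > 0 else 1.0
    im = ax.imshow(gmap.matrix_form, cmap="RdBu", vmin=-vmax, vmax=vmax)
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    ax.set_title(f"state {gmap.state + 1} saliency (1/$\\AA$)")
    plt.colorbar(im, ax=ax)
    return ax
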