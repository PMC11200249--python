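"""Neural soft Markov state models trained on time-lagged frame pairs.

A soft MSM is a nonlinear map chi from the feature vector of a frame to an
M-state probability simplex.  Following the VAMPnet approach, chi is trained
on pairs of frames (t, t + tau) from the same trajectory so that the learned
state functions capture the slowest dynamical modes: the objective is the
VAMP-E variational score built from the instantaneous (C00), time-lagged
(Ctt) and cross (C0t) covariance matrices of the state probabilities,

    score = tr[ C00^-1 C0t Ctt^-1 C0t^T ],

the sum of squared singular values of C00^{-1/2} C0t Ctt^{-1/2}.  The score
is bounded by 1 + sum_i lambda_i^2 over the eigenvalues of the underlying
transition operator, with the leading singular value 1 contributed by the
constant function; maximizing it is the variational principle.

For each system an ensemble of N models is built (default N = 20): the frame
pairs are divided into N random splits (90% training / 10% validation), and
for each split several models are trained from different initializations
(default 3), keeping the one with the highest validation VAMP-E score.  The
ensemble's soft assignment of a frame is the average of its state
probabilities across the (alignment-corrected) models; the hard assignment
is the argmax of the soft assignment.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from ._mlp import MLP, Adam
from .features import TrajectoryDataset

__all__ = [
    "Standardizer",
    "FramePairSet",
    "TrainConfig",
    "SoftModel",
    "ModelEnsemble",
    "make_frame_pairs",
    "split_pairs",
    "vamp_e_score",
    "train_model",
    "train_ensemble",
    "soft_assign",
    "hard_assign",
    "derive_seed",
    "save_ensemble",
    "load_ensemble",
]

logger = logging.getLogger(__name__)


def derive_seed(master_seed: int, *key: int) -> int:
    """Expand a master seed into an independent stream seed for (split, init, ...).

    Counter-based: uses numpy's SeedSequence with the key as spawn path, so
    every (master, key) combination yields a reproducible, decorrelated seed.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class Standardizer:
    """Per-feature affine map x -> (x - mean) / scale fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, floor: float = 1e-8) -> "Standardizer":
        x = np.asarray(x, dtype=np.float64)
        return cls(mean=x.mean(axis=0), scale=np.maximum(x.std(axis=0), floor))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.scale


@dataclass
class FramePairSet:
    """Feature vectors of frames at t (``x0``) and t + tau (``x1``).

    Both members of every pair come from the same trajectory; pairs never
    straddle trajectory boundaries.
    """

    x0: np.ndarray
    x1: np.ndarray
    lag_steps: int
    split_id: int = -1
    role: str = "all"
    traj_ids: np.ndarray | None = None  # source trajectory of each pair

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=np.float64)
        self.x1 = np.asarray(self.x1, dtype=np.float64)
        if self.x0.shape != self.x1.shape:
            raise ValueError("x0 and x1 must have identical shapes")
        if self.traj_ids is not None:
            self.traj_ids = np.asarray(self.traj_ids, dtype=np.int64)

    def __len__(self) -> int:
        return self.x0.shape[0]

    @property
    def n_features(self) -> int:
        return self.x0.shape[1]

    def subset(self, idx: np.ndarray, split_id: int, role: str) -> "FramePairSet":
        ids = None if self.traj_ids is None else self.traj_ids[idx]
        return FramePairSet(self.x0[idx], self.x1[idx], self.lag_steps,
                            split_id, role, ids)


def make_frame_pairs(dataset: TrajectoryDataset, lag_steps: int) -> FramePairSet:
    """All (frame_t, frame_{t+tau}) pairs, per trajectory, at lag ``lag_steps``."""
    if lag_steps < 1:
        raise ValueError(f"lag_steps must be >= 1, got {lag_steps}")
    x0s, x1s, ids = [], [], []
    for i, t in enumerate(dataset.trajectories):
        if t.shape[0] > lag_steps:
            x0s.append(t[:-lag_steps])
            x1s.append(t[lag_steps:])
            ids.append(np.full(t.shape[0] - lag_steps, i, dtype=np.int64))
    if not x0s:
        raise ValueError(
            f"no trajectory is longer than the lag ({lag_steps} steps); no pairs exist"
        )
    return FramePairSet(np.concatenate(x0s), np.concatenate(x1s), lag_steps,
                        traj_ids=np.concatenate(ids))


def split_pairs(pairs: FramePairSet, n_splits: int, train_fraction: float,
                seed: int, by: str = "pairs") -> list[tuple[FramePairSet, FramePairSet]]:
    """``n_splits`` independent random (train, validation) partitions.

    ``by="pairs"`` (the standard protocol) shuffles individual pairs;
    ``by="trajectories"`` assigns whole source trajectories to one side,
    for users worried about temporal leakage between train and validation.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if by not in ("pairs", "trajectories"):
        raise ValueError(f"by must be 'pairs' or 'trajectories', got {by!r}")
    p = len(pairs)
    n_train = int(round(train_fraction * p))
    if n_train < 1 or p - n_train < 1:
        raise ValueError(
            f"{p} pairs cannot be split {train_fraction:.0%}/{1 - train_fraction:.0%} "
            "with at least one pair on each side"
        )
    if by == "trajectories" and pairs.traj_ids is None:
        raise ValueError("trajectory-block splitting needs pairs with traj_ids")
    out = []
    for s in range(n_splits):
        rng = np.random.default_rng(derive_seed(seed, s))
        if by == "pairs":
            perm = rng.permutation(p)
            train_idx, val_idx = perm[:n_train], perm[n_train:]
        else:
            uniq = rng.permutation(np.unique(pairs.traj_ids))
            if len(uniq) < 2:
                raise ValueError("trajectory-block splitting needs >= 2 trajectories")
            counts = {u: int(np.sum(pairs.traj_ids == u)) for u in uniq}
            train_trajs, total = [], 0
            for u in uniq:
                if total < n_train or not train_trajs:
                    train_trajs.append(u)
                    total += counts[u]
            if len(train_trajs) == len(uniq):
                train_trajs = train_trajs[:-1]  # keep at least one block out
            mask = np.isin(pairs.traj_ids, train_trajs)
            train_idx, val_idx = np.nonzero(mask)[0], np.nonzero(~mask)[0]
        out.append((
            pairs.subset(train_idx, s, "train"),
            pairs.subset(val_idx, s, "validation"),
        ))
    return out


# ---------------------------------------------------------------------------
# VAMP-E score and its analytic gradient
# ---------------------------------------------------------------------------

def _covariances(x: np.ndarray, y: np.ndarray, eps: float):
    p = x.shape[0]
    c00 = x.T @ x / p + eps * np.eye(x.shape[1])
    ctt = y.T @ y / p + eps * np.eye(y.shape[1])
    c0t = x.T @ y / p
    return c00, c0t, ctt


def _vamp_score_probs(x: np.ndarray, y: np.ndarray, eps: float) -> float:
    c00, c0t, ctt = _covariances(x, y, eps)
    a = np.linalg.inv(c00)
    b = np.linalg.inv(ctt)
    return float(np.trace(a @ c0t @ b @ c0t.T))


def _vamp_score_grad(x: np.ndarray, y: np.ndarray, eps: float):
    """Score and its gradient with respect to the two probability batches.

    With A = C00^-1, B = Ctt^-1 the trace form differentiates to
      dL/dC0t =  2 A C0t B
      dL/dC00 = -A C0t B C0t^T A
      dL/dCtt = -B C0t^T A C0t B
    pushed through C00 = X^T X / P etc.
    """
    p = x.shape[0]
    c00, c0t, ctt = _covariances(x, y, eps)
    a = np.linalg.inv(c00)
    b = np.linalg.inv(ctt)
    acb = a @ c0t @ b
    score = float(np.trace(acb @ c0t.T))
    g0t = 2.0 * acb
    g00 = -acb @ c0t.T @ a
    gtt = -b @ c0t.T @ acb
    dx = (2.0 * x @ g00 + y @ g0t.T) / p
    dy = (2.0 * y @ gtt + x @ g0t) / p
    return score, dx, dy


@dataclass
class SoftModel:
    """A trained state-assignment function chi with its metadata."""

    net: MLP
    standardizer: Standardizer
    lag_steps: int
    validation_vamp_e: float = float("nan")
    init_seed: int = -1
    below_baseline: bool = False  # validation score under the M=1 constant model's 1.0

    @property
    def n_states(self) -> int:
        return self.net.n_out

    @property
    def n_features(self) -> int:
        return self.net.n_in

    def predict(self, frames: np.ndarray) -> np.ndarray:
        """State probabilities, shape (n_frames, M); rows sum to 1."""
        frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
        return self.net.forward(self.standardizer.transform(frames))


def vamp_e_score(model: SoftModel, pairs: FramePairSet, eps: float = 1e-10) -> float:
    """VAMP-E score of the model's state probabilities over the given pairs.

    Deterministic for fixed model and pairs.  The constant M=1 model scores
    1.0; a perfect indicator function of a Markov chain approaches
    1 + sum of squared non-unit eigenvalues as the pair count grows.
    """
    if pairs.n_features != model.n_features:
        raise ValueError("model and pairs disagree on feature dimension")
    if len(pairs) < model.n_states:
        raise ValueError(
            f"{len(pairs)} pairs cannot support an M={model.n_states} covariance "
            "estimate (singular); provide more pairs or increase regularization"
        )
    x = model.predict(pairs.x0)
    y = model.predict(pairs.x1)
    return _vamp_score_probs(x, y, eps)


@dataclass
class TrainConfig:
    """Training hyperparameters for a single soft-MSM network.

    Defaults suit full-size peptide datasets (780 features); synthetic tests
    use much smaller nets, e.g. ``hidden=(32,)``.
    """

    hidden: tuple[int, ...] = (100, 100, 100, 100)
    activation: str = "tanh"  # "selu" = self-normalizing alternative
    learning_rate: float = 1e-3
    batch_size: int = 1024
    max_epochs: int = 100
    patience: int = 10
    reg_eps: float = 1e-6

    def __post_init__(self) -> None:
        self.hidden = tuple(int(h) for h in self.hidden)


def train_model(train: FramePairSet, validation: FramePairSet, n_states: int,
                config: TrainConfig | None = None, seed: int = 0) -> SoftModel:
    """Train one soft-MSM network by Adam ascent on the minibatch VAMP-E score.

    Early-stops on the validation VAMP-E score (patience per config); the
    best-validation weights are restored.  Fully deterministic given
    (train, validation, config, seed).
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if len(train) == 0:
        raise ValueError("empty training set")
    config = config or TrainConfig()
    rng = np.random.default_rng(seed)
    std = Standardizer.fit(np.concatenate([train.x0, train.x1]))
    net = MLP.init(train.n_features, config.hidden, n_states, config.activation, rng)
    opt = Adam(net, lr=config.learning_rate)
    x0 = std.transform(train.x0)
    x1 = std.transform(train.x1)
    model = SoftModel(net, std, train.lag_steps, init_seed=seed)

    best_score = -np.inf
    best_weights = None
    bad_epochs = 0
    n = len(train)
    bs = min(config.batch_size, n)
    min_batch = max(4 * n_states, 8)
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            if len(idx) < min_batch:
                continue
            p0, cache0 = net.forward(x0[idx], cache=True)
            p1, cache1 = net.forward(x1[idx], cache=True)
            score, d0, d1 = _vamp_score_grad(p0, p1, config.reg_eps)
            if not np.isfinite(score):
                raise FloatingPointError(
                    f"non-finite training score at epoch {epoch} (seed {seed}); "
                    "reduce the learning rate or increase reg_eps"
                )
            dw0, db0 = net.backward(cache0, d0)
            dw1, db1 = net.backward(cache1, d1)
            opt.step_ascent([a + b for a, b in zip(dw0, dw1)],
                            [a + b for a, b in zip(db0, db1)])
        val = vamp_e_score(model, validation, eps=config.reg_eps)
        if val > best_score + 1e-9:
            best_score = val
            best_weights = ([w.copy() for w in net.weights],
                            [b.copy() for b in net.biases])
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > config.patience:
                break
    if best_weights is not None:
        net.weights, net.biases = best_weights
    model.validation_vamp_e = best_score
    model.below_baseline = best_score < 1.0
    if model.below_baseline:
        logger.warning("validation VAMP-E %.4f below the M=1 baseline of 1.0", best_score)
    return model


@dataclass
class ModelEnsemble:
    """N aligned soft MSMs for one system.

    ``state_permutations[n][m]`` is the common (cluster) label of state m of
    model n; ``state_feature_matrices[n, c]`` is the average feature vector
    (xi-bar) of common state c under model n, in the aligned order.
    """

    models: list[SoftModel]
    state_permutations: list[np.ndarray] | None = None
    state_feature_matrices: np.ndarray | None = None  # (N, M, F), aligned order
    system_label: str = "system"

    def __post_init__(self) -> None:
        ms = {m.n_states for m in self.models}
        lags = {m.lag_steps for m in self.models}
        dims = {m.n_features for m in self.models}
        if len(ms) != 1 or len(lags) != 1 or len(dims) != 1:
            raise ValueError("all ensemble members must share M, lag and feature dimension")

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def n_states(self) -> int:
        return self.models[0].n_states

    @property
    def lag_steps(self) -> int:
        return self.models[0].lag_steps

    @property
    def aligned(self) -> bool:
        return self.state_permutations is not None

    def aligned_probs(self, n: int, frames: np.ndarray) -> np.ndarray:
        """Model n's state probabilities reordered to the common state labels."""
        if not self.aligned:
            raise RuntimeError("ensemble is not aligned; run align_within_system first")
        p = self.models[n].predict(frames)
        out = np.empty_like(p)
        out[:, self.state_permutations[n]] = p
        return out

    def model_state_for(self, n: int, common_state: int) -> int:
        """The output index of model n that carries the given common label."""
        return int(np.nonzero(self.state_permutations[n] == common_state)[0][0])


def train_ensemble(dataset: TrajectoryDataset, n_states: int, lag_steps: int,
                   n_models: int = 20, inits_per_split: int = 3,
                   config: TrainConfig | None = None, seed: int = 0,
                   system_label: str = "system",
                   xi_weighting: str = "soft",
                   split_by: str = "pairs") -> ModelEnsemble:
    """Train, select and align an N-model soft-MSM ensemble.

    For each of ``n_models`` random 90/10 splits, ``inits_per_split`` models
    are trained from seeds derived from the master seed and the one with the
    highest validation VAMP-E is retained.  The retained models are then
    aligned to a common state order by constrained k-means on their per-state
    average feature matrices (see :mod:`vampens.alignment`).
    """
    from . import alignment  # deferred: alignment also consumes ensembles

    config = config or TrainConfig()
    pairs = make_frame_pairs(dataset, lag_steps)
    splits = split_pairs(pairs, n_models, 0.9, derive_seed(seed, 0xA11), by=split_by)
    models: list[SoftModel] = []
    for s, (tr, va) in enumerate(splits):
        candidates = []
        failures = []
        for i in range(inits_per_split):
            try:
                candidates.append(
                    train_model(tr, va, n_states, config, derive_seed(seed, s, i))
                )
            except FloatingPointError as err:  # pragma: no cover - rare
                failures.append(str(err))
        if not candidates:
            raise RuntimeError(f"all trainings failed for split {s}: {failures}")
        best = max(candidates, key=lambda m: m.validation_vamp_e)
        logger.info("split %d: kept init seed %d, validation VAMP-E %.4f",
                    s, best.init_seed, best.validation_vamp_e)
        models.append(best)
    ensemble = ModelEnsemble(models=models, system_label=system_label)
    frames = dataset.concatenated()
    xi_raw = alignment.state_feature_matrices(models, frames, weighting=xi_weighting)
    within = alignment.align_within_system(
        xi_raw, init_model=None, seed=derive_seed(seed, 0xC0), max_iter=100
    )
    ensemble.state_permutations = [p.copy() for p in within.permutations]
    aligned_xi = np.empty_like(xi_raw)
    for n in range(len(models)):
        aligned_xi[n, within.permutations[n]] = xi_raw[n]
    ensemble.state_feature_matrices = aligned_xi
    return ensemble


def soft_assign(ensemble: ModelEnsemble, frames: np.ndarray) -> np.ndarray:
    """Ensemble soft assignment: mean of permutation-corrected probabilities."""
    if not ensemble.aligned:
        raise RuntimeError("ensemble is not aligned; run align_within_system first")
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    acc = np.zeros((frames.shape[0], ensemble.n_states))
    for n in range(ensemble.n_models):
        acc += ensemble.aligned_probs(n, frames)
    return acc / ensemble.n_models


def hard_assign(ensemble: ModelEnsemble, frames: np.ndarray) -> np.ndarray:
    """Argmax of the soft assignment; ties resolve to the lowest state index."""
    return np.argmax(soft_assign(ensemble, frames), axis=1)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_ensemble(path, ensemble: ModelEnsemble, config: TrainConfig | None = None) -> None:
    """Single-file .npz checkpoint plus a JSON sidecar with the config."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "system_label": ensemble.system_label,
        "n_models": ensemble.n_models,
        "aligned": ensemble.aligned,
        "models": [],
    }
    for n, m in enumerate(ensemble.models):
        for l, (w, b) in enumerate(zip(m.net.weights, m.net.biases)):
            arrays[f"m{n}_w{l}"] = w
            arrays[f"m{n}_b{l}"] = b
        arrays[f"m{n}_mean"] = m.standardizer.mean
        arrays[f"m{n}_scale"] = m.standardizer.scale
        meta["models"].append({
            "n_layers": len(m.net.weights),
            "activation": m.net.activation,
            "lag_steps": m.lag_steps,
            "validation_vamp_e": m.validation_vamp_e,
            "init_seed": m.init_seed,
            "below_baseline": m.below_baseline,
        })
    if ensemble.aligned:
        for n, p in enumerate(ensemble.state_permutations):
            arrays[f"perm{n}"] = np.asarray(p, dtype=np.int64)
        arrays["xi"] = ensemble.state_feature_matrices
    np.savez(path, **arrays)
    sidecar = {"meta": meta}
    if config is not None:
        sidecar["train_config"] = asdict(config)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_ensemble(path) -> ModelEnsemble:
    path = Path(path)
    data = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())["meta"]
    models = []
    for n, mm in enumerate(meta["models"]):
        ws = [data[f"m{n}_w{l}"] for l in range(mm["n_layers"])]
        bs = [data[f"m{n}_b{l}"] for l in range(mm["n_layers"])]
        models.append(SoftModel(
            net=MLP(ws, bs, mm["activation"]),
            standardizer=Standardizer(data[f"m{n}_mean"], data[f"m{n}_scale"]),
            lag_steps=mm["lag_steps"],
            validation_vamp_e=mm["validation_vamp_e"],
            init_seed=mm["init_seed"],
            below_baseline=mm["below_baseline"],
        ))
    ensemble = ModelEnsemble(models=models, system_label=meta["system_label"])
    if meta["aligned"]:
        ensemble.state_permutations = [data[f"perm{n}"] for n in range(len(models))]
        ensemble.state_feature_matrices = data["xi"]
    return ensemble
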