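"""Ground-truth-known synthetic datasets for every pipeline stage.

Frames are emitted by a hidden Markov chain over K metastable states.  Each
state has a distance-like emission mean in feature space (an R-residue
"pseudo-peptide" whose base inter-residue distances grow with sequence
separation), and states differ on a designated block B of feature indices —
so both state recovery and the saliency analysis have a known answer.
Emission noise is Gaussian truncated at zero to keep features distance-like.
The chain starts from its stationary distribution, so empirical state
frequencies estimate pi without burn-in.

The default fixture is K = 3 states on R = 12 pseudo-residues (45 features)
with transition matrix

    [[0.98, 0.015, 0.005],
     [0.03, 0.95,  0.02 ],
     [0.01, 0.04,  0.95 ]]

whose eigenvalues are exactly (1, 0.96, 0.92) and stationary distribution
(0.53125, 0.296875, 0.171875).  State offsets of 3 A on 8 block features at
noise sigma = 1 A put the Bayes error around 1e-5, i.e. the states are
cleanly separable but not trivially so after standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import TrajectoryDataset, feature_count, pair_index
from .vampnet import derive_seed

__all__ = [
    "SyntheticSystemSpec",
    "GroundTruth",
    "TwoSystemGroundTruth",
    "generate_hmm_dataset",
    "default_fixture",
    "two_system_fixture",
    "bayes_posterior",
    "stationary_distribution",
]


def stationary_distribution(transition_matrix: np.ndarray) -> np.ndarray:
    """Left unit eigenvector of a row-stochastic matrix, normalized to 1."""
    vals, vecs = np.linalg.eig(np.asarray(transition_matrix, dtype=np.float64).T)
    pi = np.abs(vecs[:, np.argmax(vals.real)].real)
    return pi / pi.sum()


@dataclass
class SyntheticSystemSpec:
    """Everything needed to simulate one system, fully seed-determined."""

    transition_matrix: np.ndarray          # (K, K), row-stochastic
    emission_means: np.ndarray             # (K, F), non-negative, Angstrom
    noise_sigma: float
    n_residues: int
    n_trajectories: int
    frames_per_trajectory: int
    seed: int
    block: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    label: str = "synthetic"

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        self.emission_means = np.asarray(self.emission_means, dtype=np.float64)
        t = self.transition_matrix
        if t.ndim != 2 or t.shape[0] != t.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(t < 0) or not np.allclose(t.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("transition matrix must be row-stochastic")
        if self.n_residues < 4:
            raise ValueError("need at least 4 pseudo-residues")
        if self.emission_means.shape != (t.shape[0], feature_count(self.n_residues)):
            raise ValueError("emission_means must have shape (K, (R-2)(R-3)/2)")
        if np.any(self.emission_means < 0):
            raise ValueError("emission means must be non-negative (distances)")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.emission_means.shape[1]

    @property
    def stationary(self) -> np.ndarray:
        return stationary_distribution(self.transition_matrix)


@dataclass
class GroundTruth:
    """Hidden-state labels and generator parameters for one simulated dataset."""

    labels: list[np.ndarray]          # per trajectory, values in 0..K-1
    stationary: np.ndarray
    emission_means: np.ndarray
    block: np.ndarray

    def all_labels(self) -> np.ndarray:
        return np.concatenate(self.labels)


def generate_hmm_dataset(spec: SyntheticSystemSpec) -> tuple[TrajectoryDataset, GroundTruth]:
    """Simulate the hidden chain and emit truncated-Gaussian features."""
    pi = spec.stationary
    cum_t = np.cumsum(spec.transition_matrix, axis=1)
    trajs, labels = [], []
    for traj_idx in range(spec.n_trajectories):
        rng = np.random.default_rng(derive_seed(spec.seed, traj_idx))
        n = spec.frames_per_trajectory
        states = np.empty(n, dtype=np.int64)
        states[0] = rng.choice(spec.n_states, p=pi)
        u = rng.random(n)
        for t in range(1, n):
            states[t] = np.searchsorted(cum_t[states[t - 1]], u[t])
        noise = rng.normal(0.0, spec.noise_sigma, size=(n, spec.n_features))
        frames = np.maximum(spec.emission_means[states] + noise, 0.0)
        trajs.append(frames)
        labels.append(states)
    dataset = TrajectoryDataset(trajectories=trajs,
                                labels=[f"{spec.label}_{i:03d}" for i in range(len(trajs))])
    truth = GroundTruth(labels=labels, stationary=pi,
                        emission_means=spec.emission_means.copy(),
                        block=spec.block.copy())
    return dataset, truth


def _base_means(n_residues: int) -> np.ndarray:
    """Distance-like base feature vector: grows with sequence separation."""
    pairs = pair_index(n_residues)
    sep = (pairs[:, 1] - pairs[:, 0]).astype(np.float64)
    return 6.0 + 1.2 * sep


DEFAULT_TRANSITIONS = np.array([
    [0.98, 0.015, 0.005],
    [0.03, 0.95, 0.02],
    [0.01, 0.04, 0.95],
])


def default_fixture(n_trajectories: int = 10, frames_per_trajectory: int = 10_000,
                    noise_sigma: float = 1.0, seed: int = 0,
                    label: str = "synthetic") -> SyntheticSystemSpec:
    """The canonical 3-state, 12-pseudo-residue (45-feature) fixture.

    The discriminative block B consists of the 15 pairs lying entirely
    within the first 8 residues; state 2 shifts the first 8 block features
    by +3 A, state 3 the last 8 (one overlapping pair).
    """
    n_residues = 12
    pairs = pair_index(n_residues)
    block = np.nonzero((pairs[:, 0] < 8) & (pairs[:, 1] < 8))[0]
    base = _base_means(n_residues)
    means = np.tile(base, (3, 1))
    means[1, block[:8]] += 3.0
    means[2, block[-8:]] += 3.0
    return SyntheticSystemSpec(
        transition_matrix=DEFAULT_TRANSITIONS.copy(),
        emission_means=means,
        noise_sigma=noise_sigma,
        n_residues=n_residues,
        n_trajectories=n_trajectories,
        frames_per_trajectory=frames_per_trajectory,
        seed=seed,
        block=block,
        label=label,
    )


def bayes_posterior(spec: SyntheticSystemSpec, frames: np.ndarray) -> np.ndarray:
    """Posterior state probabilities of the (untruncated) emission model.

    Isotropic Gaussian likelihoods with the stationary prior — the
    Bayes-optimal soft classifier for the generator, used as an independent
    oracle against trained models.  Truncation at zero is ignored, which is
    negligible when the means exceed a few sigma.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    d2 = ((frames[:, None, :] - spec.emission_means[None]) ** 2).sum(axis=2)
    logp = -0.5 * d2 / spec.noise_sigma ** 2 + np.log(spec.stationary)[None]
    logp -= logp.max(axis=1, keepdims=True)
    p = np.exp(logp)
    return p / p.sum(axis=1, keepdims=True)


@dataclass
class TwoSystemGroundTruth:
    """Recorded correspondence between the states of the paired fixtures.

    ``permutation[k]`` is the state label in system 2 that carries (a
    possibly perturbed copy of) state k of system 1; ``shared[k]`` is True
    when that state's emissions were left untouched.
    """

    permutation: np.ndarray
    shared: np.ndarray
    perturbation: float


def two_system_fixture(shared_states: int = 2, perturbation: float = 4.0,
                       seed: int = 0, **fixture_kwargs):
    """Pair of system specs sharing a subset of states.

    System 2 copies system 1 but (i) perturbs the emission means of the
    K - shared_states last states by ``perturbation`` (added to their block
    features, pushing their Wasserstein distance well past T_e) and
    (ii) relabels all states by a seed-drawn permutation, recorded in the
    returned ground truth.  System 2 also gets its own simulation seed.
    """
    if perturbation <= 0:
        raise ValueError("perturbation must be positive")
    spec1 = default_fixture(seed=derive_seed(seed, 1), label="system1", **fixture_kwargs)
    k = spec1.n_states
    if not 1 <= shared_states <= k:
        raise ValueError(f"shared_states must be in 1..{k}")
    rng = np.random.default_rng(derive_seed(seed, 2))
    perm = rng.permutation(k)

    means2 = spec1.emission_means.copy()
    shared = np.zeros(k, dtype=bool)
    shared[:shared_states] = True
    for state in range(shared_states, k):
        means2[state, spec1.block] += perturbation

    t2 = np.empty_like(spec1.transition_matrix)
    m2 = np.empty_like(means2)
    t2[np.ix_(perm, perm)] = spec1.transition_matrix
    m2[perm] = means2
    spec2 = replace(spec1, transition_matrix=t2, emission_means=m2,
                    seed=derive_seed(seed, 3), label="system2")
    return spec1, spec2, TwoSystemGroundTruth(perm, shared, float(perturbation))
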