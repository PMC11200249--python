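"""Aligning learned states within one system and across systems.

The state order on a trained network's output is arbitrary, so two kinds of
correspondence must be established before ensembles can be averaged or two
systems compared:

* **Within a system** — the N models of an ensemble are aligned by a
  constrained k-means over their per-state average feature matrices
  (xi-bar): cluster centers are initialized from one model's matrices, every
  model's states are then assigned greedily to *distinct* clusters in order
  of proximity, and centers are recomputed as member means, iterating until
  the assignment is stable.  The constraint (no two states of one model in
  the same cluster) makes each model's assignment a permutation.

* **Across two systems** — each common state m of a system is characterized
  by the empirical distribution of its N xi-bar matrices over the ensemble
  (a uniform mixture of Dirac atoms in feature space).  The cost of aligning
  state m of system 1 with state l of system 2 is the Wasserstein-1 distance
  between these distributions under the Euclidean ground metric, computed by
  the optimal-transport linear program.  The optimal bijection of the
  smaller state set into the larger is found by the Hungarian algorithm on
  the cost matrix, and a pair counts as genuinely matched only if its cost
  is below the empirical threshold T_e (default 6, in the Angstrom units of
  the feature space).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

__all__ = [
    "StateDistribution",
    "WithinAlignment",
    "CrossAlignment",
    "state_feature_matrices",
    "align_within_system",
    "wasserstein1",
    "cost_matrix",
    "align_across_systems",
    "ensemble_state_distributions",
]

DEFAULT_THRESHOLD = 6.0  # T_e, empirical matched/unmatched cutoff (Angstrom)


# ---------------------------------------------------------------------------
# xi-bar matrices
# ---------------------------------------------------------------------------

def state_feature_matrices(models, frames: np.ndarray,
                           weighting: str = "soft") -> np.ndarray:
    """Per-model per-state average feature vectors xi-bar, shape (N, M, F).

    ``weighting="soft"`` uses probability-weighted means; ``"hard"`` averages
    only the frames whose argmax assignment under that model is the state.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.float64))
    if frames.shape[0] == 0:
        raise ValueError("empty frame sample")
    if weighting not in ("soft", "hard"):
        raise ValueError(f"weighting must be 'soft' or 'hard', got {weighting!r}")
    n_models = len(models)
    n_states = models[0].n_states
    xi = np.empty((n_models, n_states, frames.shape[1]))
    for n, model in enumerate(models):
        probs = model.predict(frames)
        if weighting == "hard":
            w = np.zeros_like(probs)
            w[np.arange(len(probs)), np.argmax(probs, axis=1)] = 1.0
        else:
            w = probs
        mass = w.sum(axis=0)
        for m in range(n_states):
            if mass[m] < 1e-8:
                raise ValueError(
                    f"state {m + 1} of model {n + 1} has total weight {mass[m]:.2e}; "
                    "it is never populated on the given frames"
                )
            xi[n, m] = (w[:, m][:, None] * frames).sum(axis=0) / mass[m]
    return xi


# ---------------------------------------------------------------------------
# Within-system alignment: constrained k-means
# ---------------------------------------------------------------------------

@dataclass
class WithinAlignment:
    """Result of the constrained k-means over xi-bar matrices.

    ``permutations[n][m]`` is the cluster (common state) label assigned to
    state m of model n; each row is a bijection on {0..M-1}.
    """

    permutations: list[np.ndarray]
    cluster_centers: np.ndarray  # (M, F)
    n_iterations: int
    converged: bool


def _greedy_constrained_assign(xi_model: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Assign each state of one model to a distinct cluster.

    All (state, cluster) distances are sorted globally ascending and accepted
    greedily subject to the bijection constraint; ties break on lower state
    index, then lower cluster index.
    """
    n_states = xi_model.shape[0]
    d = cdist(xi_model, centers)
    order = np.argsort(d, axis=None, kind="stable")
    perm = np.full(n_states, -1, dtype=np.int64)
    used = np.zeros(n_states, dtype=bool)
    assigned = 0
    for flat in order:
        m, c = divmod(int(flat), n_states)
        if perm[m] == -1 and not used[c]:
            perm[m] = c
            used[c] = True
            assigned += 1
            if assigned == n_states:
                break
    return perm


def align_within_system(xi: np.ndarray, init_model: int | None = None,
                        seed: int = 0, max_iter: int = 100,
                        try_all_inits: bool = False) -> WithinAlignment:
    """Constrained k-means alignment of an ensemble's states.

    Parameters
    ----------
    xi
        (N, M, F) per-model per-state average feature vectors.
    init_model
        Index of the model whose xi-bar matrices initialize the cluster
        centers; ``None`` (default) picks one at random using ``seed``.
    max_iter
        Iteration cap; a repeat of a previously seen assignment (cycle) also
        terminates.  ``converged`` is True only for a genuine fixed point.
    try_all_inits
        Run every model as the initialization and keep the result with the
        lowest within-cluster variance (extension beyond the single random
        initialization; off by default).
    """
    xi = np.asarray(xi, dtype=np.float64)
    if xi.ndim != 3:
        raise ValueError("xi must have shape (n_models, n_states, n_features)")
    n_models, n_states, _ = xi.shape
    if try_all_inits:
        candidates = [align_within_system(xi, init_model=n, max_iter=max_iter)
                      for n in range(n_models)]
        return min(candidates, key=lambda r: _within_cluster_variance(xi, r))
    if init_model is None:
        init_model = int(np.random.default_rng(seed).integers(n_models))
    centers = xi[init_model].copy()
    perms = [np.arange(n_states, dtype=np.int64) for _ in range(n_models)]
    seen: set[bytes] = set()
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        new_perms = [_greedy_constrained_assign(xi[n], centers) for n in range(n_models)]
        for p in new_perms:  # bijection sanity: one state per model per cluster
            assert len(np.unique(p)) == n_states
        if all(np.array_equal(a, b) for a, b in zip(new_perms, perms)) and iteration > 1:
            converged = True
            perms = new_perms
            break
        perms = new_perms
        fingerprint = np.concatenate(perms).tobytes()
        if fingerprint in seen:
            break
        seen.add(fingerprint)
        for c in range(n_states):
            members = [xi[n, int(np.nonzero(perms[n] == c)[0][0])] for n in range(n_models)]
            centers[c] = np.mean(members, axis=0)
    return WithinAlignment(perms, centers, iteration, converged)


def _within_cluster_variance(xi: np.ndarray, res: WithinAlignment) -> float:
    total = 0.0
    n_models, n_states, _ = xi.shape
    for n in range(n_models):
        for m in range(n_states):
            total += float(np.sum((xi[n, m] - res.cluster_centers[res.permutations[n][m]]) ** 2))
    return total


# ---------------------------------------------------------------------------
# Cross-system alignment: Wasserstein-1 + Hungarian
# ---------------------------------------------------------------------------

@dataclass
class StateDistribution:
    """Uniform empirical distribution of one state's xi-bar over the ensemble."""

    atoms: np.ndarray  # (N, F)
    system_label: str = "system"
    state_label: int = 0

    def __post_init__(self) -> None:
        self.atoms = np.atleast_2d(np.asarray(self.atoms, dtype=np.float64))
        if self.atoms.shape[0] < 1:
            raise ValueError("a state distribution needs at least one atom")

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]


def ensemble_state_distributions(ensemble) -> list[StateDistribution]:
    """One StateDistribution per common state of an aligned ensemble."""
    if ensemble.state_feature_matrices is None:
        raise RuntimeError("ensemble has no xi-bar matrices; align it first")
    xi = ensemble.state_feature_matrices
    return [
        StateDistribution(xi[:, m, :], ensemble.system_label, m)
        for m in range(xi.shape[1])
    ]


def wasserstein1(p: StateDistribution, q: StateDistribution) -> float:
    """Wasserstein-1 distance between two uniform empirical distributions.

    Solved as the optimal-transport linear program with Euclidean ground
    cost: minimize sum_ij gamma_ij d_ij subject to uniform marginals.
    """
    if p.atoms.shape[1] != q.atoms.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {p.atoms.shape[1]} vs {q.atoms.shape[1]}"
        )
    d = cdist(p.atoms, q.atoms)
    n1, n2 = d.shape
    if n1 == 1 and n2 == 1:
        return float(d[0, 0])
    # marginal constraints; one row is redundant and dropped for full rank
    a_eq = np.zeros((n1 + n2 - 1, n1 * n2))
    b_eq = np.empty(n1 + n2 - 1)
    for i in range(n1):
        a_eq[i, i * n2:(i + 1) * n2] = 1.0
        b_eq[i] = 1.0 / n1
    for j in range(n2 - 1):
        a_eq[n1 + j, j::n2] = 1.0
        b_eq[n1 + j] = 1.0 / n2
    res = linprog(d.ravel(), A_eq=a_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - HiGHS is robust on these LPs
        raise RuntimeError(f"optimal transport LP failed: {res.message}")
    return float(res.fun)


def cost_matrix(dists1: list[StateDistribution],
                dists2: list[StateDistribution]) -> np.ndarray:
    """Pairwise Wasserstein-1 alignment costs, shape (M1, M2)."""
    return np.array([[wasserstein1(p, q) for q in dists2] for p in dists1])


@dataclass
class CrossAlignment:
    """Optimal matching of the states of two systems.

    ``mapping[m]`` is the state of the larger system matched to state m of
    the smaller one (after the internal orientation swap, recorded in
    ``swapped``: if True, the cost matrix rows belong to ``system2``).
    """

    cost: np.ndarray
    mapping: np.ndarray
    threshold: float
    matched: np.ndarray
    total_cost: float
    swapped: bool = False
    system1: str = "system1"
    system2: str = "system2"

    def to_dict(self) -> dict:
        return {
            "system1": self.system1,
            "system2": self.system2,
            "rows_are": self.system2 if self.swapped else self.system1,
            "cost": self.cost.tolist(),
            "mapping": self.mapping.tolist(),
            "threshold": self.threshold,
            "matched": self.matched.tolist(),
            "total_cost": self.total_cost,
        }


def align_across_systems(cost: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                         system1: str = "system1",
                         system2: str = "system2") -> CrossAlignment:
    """Hungarian matching of two systems' states under a cost matrix.

    Minimizes the total cost over all injections of the smaller state set
    into the larger; each pair is flagged matched when its cost is below the
    threshold T_e.
    """
    cost = np.asarray(cost, dtype=np.float64)
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix contains non-finite entries")
    swapped = cost.shape[0] > cost.shape[1]
    work = cost.T if swapped else cost
    rows, cols = linear_sum_assignment(work)
    mapping = np.empty(work.shape[0], dtype=np.int64)
    mapping[rows] = cols
    pair_costs = work[np.arange(len(mapping)), mapping]
    return CrossAlignment(
        cost=work.copy(),
        mapping=mapping,
        threshold=float(threshold),
        matched=pair_costs < threshold,
        total_cost=float(pair_costs.sum()),
        swapped=swapped,
        system1=system1,
        system2=system2,
    )
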