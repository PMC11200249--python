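"""Independent oracles used by the test suite.

Everything here is deliberately brute force (enumeration, Monte-Carlo,
finite differences) and shares no code with the implementation paths it
checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def w1_equal_size_bruteforce(atoms1: np.ndarray, atoms2: np.ndarray) -> float:
    """Wasserstein-1 between equal-size uniform empirical distributions by
    exhaustive enumeration of all permutation transport plans."""
    n = atoms1.shape[0]
    assert atoms2.shape[0] == n
    d = np.linalg.norm(atoms1[:, None, :] - atoms2[None, :, :], axis=-1)
    best = np.inf
    for perm in permutations(range(n)):
        best = min(best, sum(d[i, perm[i]] for i in range(n)) / n)
    return best


def assignment_bruteforce(cost: np.ndarray) -> tuple[np.ndarray, float]:
    """Minimum-cost injection of rows into columns by exhaustive enumeration."""
    m1, m2 = cost.shape
    assert m1 <= m2
    best_total, best_map = np.inf, None
    for cols in permutations(range(m2), m1):
        total = sum(cost[i, c] for i, c in enumerate(cols))
        if total < best_total:
            best_total, best_map = total, np.asarray(cols)
    return best_map, float(best_total)


def mc_first_passage(transition_matrix: np.ndarray, start: int, target: int,
                     n_samples: int, seed: int, max_steps: int = 100_000) -> float:
    """Monte-Carlo mean first-passage time (in steps) by direct simulation."""
    rng = np.random.default_rng(seed)
    cum = np.cumsum(transition_matrix, axis=1)
    state = np.full(n_samples, start, dtype=np.int64)
    steps = np.zeros(n_samples, dtype=np.int64)
    alive = np.ones(n_samples, dtype=bool)
    for _ in range(max_steps):
        idx = np.nonzero(alive)[0]
        if idx.size == 0:
            break
        u = rng.random(idx.size)
        state[idx] = (u[:, None] > cum[state[idx]]).sum(axis=1)
        steps[idx] += 1
        alive[idx] = state[idx] != target
    assert not alive.any(), "MC first-passage did not absorb; raise max_steps"
    return float(steps.mean())


def simulate_chain(transition_matrix: np.ndarray, n_steps: int, seed: int,
                   init: int | None = None) -> np.ndarray:
    """Plain Markov-chain path; init drawn from the stationary vector if None."""
    rng = np.random.default_rng(seed)
    t = np.asarray(transition_matrix, dtype=np.float64)
    cum = np.cumsum(t, axis=1)
    vals, vecs = np.linalg.eig(t.T)
    pi = np.abs(vecs[:, np.argmax(vals.real)].real)
    pi /= pi.sum()
    s = np.empty(n_steps, dtype=np.int64)
    s[0] = init if init is not None else rng.choice(len(pi), p=pi)
    u = rng.random(n_steps)
    for i in range(1, n_steps):
        s[i] = np.searchsorted(cum[s[i - 1]], u[i])
    return s


class IndicatorModel:
    """Duck-typed SoftModel that one-hot encodes a scalar state feature.

    Frames are expected to carry the integer state label (plus negligible
    noise) in their first feature.
    """

    def __init__(self, n_states: int, lag_steps: int = 1):
        self.n_states = n_states
        self.lag_steps = lag_steps
        self.n_features = 1

    def predict(self, frames: np.ndarray) -> np.ndarray:
        frames = np.atleast_2d(frames)
        labels = np.clip(np.rint(frames[:, 0]).astype(int), 0, self.n_states - 1)
        return np.eye(self.n_states)[labels]


class BayesModel:
    """Duck-typed SoftModel wrapping the generator's Bayes posterior."""

    def __init__(self, spec, lag_steps: int = 1):
        from vampens.synthetic_data import bayes_posterior

        self._posterior = lambda frames: bayes_posterior(spec, frames)
        self.n_states = spec.n_states
        self.n_features = spec.n_features
        self.lag_steps = lag_steps

    def predict(self, frames: np.ndarray) -> np.ndarray:
        return self._posterior(frames)


def central_fd_gradient(fn, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference gradient of a scalar function of a vector."""
    g = np.empty_like(x, dtype=np.float64)
    for i in range(x.size):
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        g[i] = (fn(xp) - fn(xm)) / (2 * h)
    return g
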