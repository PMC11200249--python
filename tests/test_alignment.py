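from itertools import permutations

import numpy as np
import pytest

from oracles import BayesModel, assignment_bruteforce, w1_equal_size_bruteforce
from vampens.alignment import (StateDistribution, align_across_systems,
                               align_within_system, cost_matrix,
                               ensemble_state_distributions,
                               state_feature_matrices, wasserstein1)
from vampens.synthetic_data import generate_hmm_dataset, two_system_fixture
from vampens.vampnet import derive_seed


def _dist(atoms, **kw):
    return StateDistribution(np.atleast_2d(np.asarray(atoms, dtype=float)), **kw)


# ---------------------------------------------------------------------------
# xi-bar matrices
# ---------------------------------------------------------------------------

class _FixedModel:
    """Duck-typed model with constant output probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)
        self.n_states = self.probs.shape[0]

    def predict(self, frames):
        return np.tile(self.probs, (np.atleast_2d(frames).shape[0], 1))


def test_all_mass_on_one_state_gives_plain_mean(rng):
    frames = rng.random((200, 6))
    xi = state_feature_matrices([_FixedModel([1.0])], frames)
    np.testing.assert_allclose(xi[0, 0], frames.mean(axis=0), atol=1e-12)


def test_uniform_soft_weights_give_global_mean(rng):
    frames = rng.random((300, 5))
    xi = state_feature_matrices([_FixedModel([1 / 3] * 3)], frames)
    for m in range(3):
        np.testing.assert_allclose(xi[0, m], frames.mean(axis=0), atol=1e-12)


def test_unpopulated_state_raises(rng):
    frames = rng.random((50, 4))
    with pytest.raises(ValueError, match="model 1"):
        state_feature_matrices([_FixedModel([1.0, 0.0])], frames)


def test_xi_matches_generator_emission_means(fixture_spec, fixture_data):
    dataset, truth = fixture_data
    frames = dataset.concatenated()[:5000]
    xi = state_feature_matrices([BayesModel(fixture_spec)], frames)
    np.testing.assert_allclose(xi[0], truth.emission_means, atol=0.15)


def test_hard_weighting_close_to_soft_on_separable_data(fixture_spec, fixture_data):
    frames = fixture_data[0].concatenated()[:3000]
    model = BayesModel(fixture_spec)
    soft = state_feature_matrices([model], frames, weighting="soft")
    hard = state_feature_matrices([model], frames, weighting="hard")
    np.testing.assert_allclose(soft, hard, atol=0.05)


# ---------------------------------------------------------------------------
# constrained k-means
# ---------------------------------------------------------------------------

def test_exact_permuted_copies_recovered(rng):
    ref = rng.random((3, 8)) * 10
    perms = [np.array([0, 1, 2]), np.array([2, 0, 1]), np.array([1, 2, 0])]
    # model n's state m is ref state perms[n][m]
    xi = np.stack([ref[p] for p in perms])
    res = align_within_system(xi, init_model=0)
    assert res.converged
    # cluster of (n, m) must equal the true identity perms[n][m]
    for n, p in enumerate(perms):
        np.testing.assert_array_equal(res.permutations[n], p)
    # zero within-cluster variance: centers equal ref exactly
    np.testing.assert_allclose(res.cluster_centers, ref, atol=1e-12)


def test_single_model_identity(rng):
    xi = rng.random((1, 4, 6))
    res = align_within_system(xi, init_model=0)
    np.testing.assert_array_equal(res.permutations[0], np.arange(4))
    assert res.converged


def test_noisy_copies_recovered_and_match_bruteforce_oracle():
    master = np.random.default_rng(99)
    ref = master.random((3, 10)) * 10
    sep = min(np.linalg.norm(ref[a] - ref[b]) for a in range(3) for b in range(a))
    sigma = 0.1 * sep
    for seed in range(10):
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(3) for _ in range(5)]
        xi = np.stack([ref[p] + rng.normal(0, sigma, size=(3, 10)) for p in perms])
        res = align_within_system(xi, init_model=0, seed=seed)
        # recovered clusters agree with generating identities up to one
        # global relabeling (anchor on model 0)
        anchor = {res.permutations[0][m]: perms[0][m] for m in range(3)}
        for n in range(5):
            for m in range(3):
                assert anchor[res.permutations[n][m]] == perms[n][m]
        # and each model's assignment is its exhaustive best vs final centers
        for n in range(5):
            best = min(permutations(range(3)),
                       key=lambda p: sum(np.linalg.norm(xi[n, m] - res.cluster_centers[p[m]]) ** 2
                                         for m in range(3)))
            np.testing.assert_array_equal(res.permutations[n], best)


def test_try_all_inits_never_worse_than_single_init(rng):
    ref = rng.random((3, 6)) * 10
    perms = [rng.permutation(3) for _ in range(4)]
    xi = np.stack([ref[p] + rng.normal(0, 0.3, (3, 6)) for p in perms])
    from vampens.alignment import _within_cluster_variance
    best = align_within_system(xi, try_all_inits=True)
    single = align_within_system(xi, init_model=2)
    assert _within_cluster_variance(xi, best) <= \
        _within_cluster_variance(xi, single) + 1e-12


def test_inconsistent_state_count_raises(rng):
    with pytest.raises(ValueError):
        align_within_system(rng.random((2, 3)), init_model=0)


# ---------------------------------------------------------------------------
# Wasserstein-1
# ---------------------------------------------------------------------------

def test_w1_identity_of_indiscernibles(rng):
    p = _dist(rng.random((4, 3)))
    assert wasserstein1(p, p) == pytest.approx(0.0, abs=1e-9)


def test_w1_single_atoms_is_euclidean():
    p, q = _dist([[0.0, 0.0]]), _dist([[3.0, 4.0]])
    assert wasserstein1(p, q) == pytest.approx(5.0)


def test_w1_shifted_triplet():
    p = _dist([[0.0], [1.0], [2.0]])
    q = _dist([[1.0], [2.0], [3.0]])
    assert wasserstein1(p, q) == pytest.approx(1.0, abs=1e-9)


def test_w1_dimension_mismatch():
    with pytest.raises(ValueError, match="dimension"):
        wasserstein1(_dist([[0.0, 1.0]]), _dist([[0.0]]))


def test_w1_equals_bruteforce_matching(rng):
    for _ in range(30):
        n = int(rng.integers(1, 7))
        d = int(rng.integers(1, 6))
        a, b = rng.random((n, d)) * 5, rng.random((n, d)) * 5
        lp = wasserstein1(_dist(a), _dist(b))
        assert lp == pytest.approx(w1_equal_size_bruteforce(a, b), abs=1e-9)


def test_w1_metric_properties(rng):
    for _ in range(20):
        d = int(rng.integers(1, 6))
        ps = [_dist(rng.random((int(rng.integers(1, 5)), d))) for _ in range(3)]
        w01 = wasserstein1(ps[0], ps[1])
        w10 = wasserstein1(ps[1], ps[0])
        w12 = wasserstein1(ps[1], ps[2])
        w02 = wasserstein1(ps[0], ps[2])
        assert w01 >= 0
        assert w01 == pytest.approx(w10, abs=1e-9)       # symmetry
        assert w02 <= w01 + w12 + 1e-9                   # triangle inequality


# ---------------------------------------------------------------------------
# cost matrix + Hungarian
# ---------------------------------------------------------------------------

def test_cost_matrix_zero_diagonal_and_transpose_symmetry(rng):
    dists1 = [_dist(rng.random((4, 3))) for _ in range(3)]
    dists2 = [_dist(rng.random((4, 3))) for _ in range(2)]
    c11 = cost_matrix(dists1, dists1)
    np.testing.assert_allclose(np.diag(c11), 0.0, atol=1e-9)
    c12 = cost_matrix(dists1, dists2)
    c21 = cost_matrix(dists2, dists1)
    np.testing.assert_allclose(c12, c21.T, atol=1e-9)


def test_hungarian_trivial_identity():
    res = align_across_systems(np.array([[0.0, 5.0], [5.0, 0.0]]))
    np.testing.assert_array_equal(res.mapping, [0, 1])
    assert res.total_cost == 0.0
    assert res.matched.all()


def test_hungarian_rectangular_matches_enumeration():
    cost = np.array([[4.0, 7.0, 1.0], [2.0, 6.0, 5.0]])
    res = align_across_systems(cost)
    np.testing.assert_array_equal(res.mapping, [2, 0])
    assert res.total_cost == pytest.approx(3.0)
    oracle_map, oracle_total = assignment_bruteforce(cost)
    np.testing.assert_array_equal(res.mapping, oracle_map)
    assert res.total_cost == pytest.approx(oracle_total)


def test_hungarian_equals_enumeration_randomized(rng):
    for _ in range(40):
        m1 = int(rng.integers(1, 6))
        m2 = int(rng.integers(m1, 7))
        cost = rng.random((m1, m2)) * 10
        res = align_across_systems(cost)
        _, oracle_total = assignment_bruteforce(cost)
        assert res.total_cost == pytest.approx(oracle_total, abs=1e-12)


def test_all_costs_above_threshold_yield_no_matches():
    res = align_across_systems(np.full((2, 2), 50.0), threshold=6.0)
    assert not res.matched.any()
    assert sorted(res.mapping.tolist()) == [0, 1]  # still a valid bijection


def test_orientation_swap_recorded():
    cost = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])  # M1=3 > M2=2
    res = align_across_systems(cost)
    assert res.swapped
    assert res.cost.shape == (2, 3)
    with pytest.raises(ValueError, match="non-finite"):
        align_across_systems(np.array([[np.nan, 1.0]]))


# ---------------------------------------------------------------------------
# end-to-end two-system recovery
# ---------------------------------------------------------------------------

def _bayes_ensemble_distributions(spec, n_members=5, frames_cap=6000):
    """State distributions from Bayes-classifier xi-bars over disjoint frame
    subsets, one subset per ensemble member."""
    dataset, _ = generate_hmm_dataset(spec)
    frames = dataset.concatenated()[:frames_cap * n_members]
    model = BayesModel(spec)
    xi = np.stack([
        state_feature_matrices([model], frames[k * frames_cap:(k + 1) * frames_cap])[0]
        for k in range(n_members)
    ])
    return [StateDistribution(xi[:, m, :], spec.label, m) for m in range(spec.n_states)]


@pytest.mark.parametrize("seed", [0, 1])
def test_two_system_recovery_with_threshold(seed):
    spec1, spec2, truth = two_system_fixture(shared_states=2, seed=seed,
                                             n_trajectories=4,
                                             frames_per_trajectory=8000)
    d1 = _bayes_ensemble_distributions(spec1)
    d2 = _bayes_ensemble_distributions(spec2)
    cost = cost_matrix(d1, d2)
    res = align_across_systems(cost, threshold=6.0)
    assert not res.swapped
    np.testing.assert_array_equal(res.mapping, truth.permutation)
    np.testing.assert_array_equal(res.matched, truth.shared)


def test_two_system_recovery_trained_end_to_end():
    """Full loop with trained networks: shared states align cheaply, the
    perturbed state stays above threshold."""
    from conftest import FIXTURE_LAG
    from vampens.vampnet import TrainConfig, train_ensemble

    spec1, spec2, truth = two_system_fixture(shared_states=2, seed=5,
                                             n_trajectories=3,
                                             frames_per_trajectory=4000)
    cfg = TrainConfig(hidden=(16,), batch_size=2048, max_epochs=15, patience=3,
                      learning_rate=5e-3)
    dists = []
    specs = [spec1, spec2]
    for sys_idx, spec in enumerate(specs):
        dataset, _ = generate_hmm_dataset(spec)
        ens = train_ensemble(dataset, 3, FIXTURE_LAG, n_models=3,
                             inits_per_split=1, config=cfg,
                             seed=derive_seed(5, sys_idx),
                             system_label=spec.label)
        dists.append(ensemble_state_distributions(ens))
    cost = cost_matrix(dists[0], dists[1])
    res = align_across_systems(cost, threshold=6.0)
    # trained state labels are arbitrary: identify each learned state by its
    # nearest generator emission mean, then check consistency with the truth
    ident = []
    for dset, spec in zip(dists, specs):
        ident.append([
            int(np.argmin(np.linalg.norm(
                spec.emission_means - d.atoms.mean(axis=0), axis=1)))
            for d in dset
        ])
    for m in range(3):
        true_state_sys1 = ident[0][m]
        mapped = ident[1][res.mapping[m]]
        assert mapped == truth.permutation[true_state_sys1]
        assert res.matched[m] == truth.shared[true_state_sys1]
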