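# vampens

**Ensembles of neural soft Markov state models for comparing conformational
dynamics across systems.**

Intrinsically disordered peptides and proteins do not fold into one
structure; molecular-dynamics simulations of them produce broad
conformational ensembles whose kinetics are naturally summarized by a
Markov state model (MSM) — a small set of metastable states with a
transition-probability matrix T(τ) at a lag time τ. When the question is
*how a ligand changes that ensemble*, three problems appear at once:

1. classical MSM pipelines hard-partition conformations, losing gradation;
2. a single trained model gives no error bars, and independently trained
   models order their states arbitrarily, so they cannot be averaged or
   compared as they stand;
3. even once each system has a consistent model ensemble, the states of
   *different* systems (e.g. free peptide vs peptide + ligand) must be put
   into correspondence before any "state X shrank, state Y is new" claim.

`vampens` addresses all three with a single pipeline, aimed at
computational structural biologists who already have feature trajectories
(or PDB/XTC/DCD files) in hand:

- **Soft MSMs by variational training.** A feed-forward network
  χ: ℝ^F → Δ^{M−1} maps the frame's inter-residue distance features
  (the (R−2)(R−3)/2-vector of the distance matrix's upper triangle without
  the first two off-diagonals; 780 features for a 42-residue peptide) to
  state probabilities, trained on time-lagged frame pairs by maximizing the
  VAMP-E score tr[C00⁻¹C0τCττ⁻¹C0τᵀ] of the lagged covariances of its own
  outputs — the variational principle that makes the learned states capture
  the slowest processes. Per system, 20 random 90/10 splits × 3
  initializations, keeping the best validation score per split, give a
  20-model ensemble with genuine spread.
- **Alignment within a system** by constrained k-means over the per-state
  mean feature matrices ξ̄ (no two states of one model may share a
  cluster), yielding per-model state permutations.
- **Alignment across systems** by optimal transport: each state is the
  uniform empirical distribution of its N ξ̄ matrices; the pairwise cost is
  the Wasserstein-1 distance (linear program); the optimal bijection comes
  from the Hungarian algorithm; matches costlier than T_e (default 6 Å) are
  declared "no counterpart".
- **Kinetics** from reversible, non-negative transition-matrix estimates on
  soft counts: equilibrium distributions, mean first-passage times, implied
  timescales, Chapman–Kolmogorov validation, with median-centered 95%
  ensemble bands.
- **Interpretation**: exact per-state saliency g_m = ensemble-averaged
  ∇_ξ χ_m over 10,000 random frames — positive entries mean "this state
  becomes more likely when this inter-residue distance grows" — rendered as
  R×R maps and per-residue profiles; plus free-energy surfaces
  F = −ln p̂ (kT) from Gaussian KDE on a 10% subsample of the leading
  two-component tICA projection.

A synthetic-data module generates hidden-Markov datasets with known
transition matrices, emission means and two-system shared-state fixtures,
so every stage of the pipeline is testable against ground truth without any
simulation data. See `docs/methods.md` for models, conventions and
numerical details.

## Worked example

```python
import numpy as np
from vampens import (default_fixture, generate_hmm_dataset, train_ensemble,
                     TrainConfig, ensemble_kinetics, ensemble_gradient,
                     soft_assign)

# synthetic 3-state system: 12 pseudo-residues -> 45 distance features,
# transition-matrix eigenvalues exactly (1, 0.96, 0.92)
spec = default_fixture(n_trajectories=4, frames_per_trajectory=5000, seed=123)
dataset, truth = generate_hmm_dataset(spec)

config = TrainConfig(hidden=(32,), batch_size=4096, max_epochs=40,
                     patience=5, learning_rate=5e-3)
ensemble = train_ensemble(dataset, n_states=3, lag_steps=5,
                          n_models=3, inits_per_split=1,
                          config=config, seed=2024)

summary = ensemble_kinetics(ensemble, dataset)
print("generator stationary:", np.round(truth.stationary, 4))
print("estimated (median):  ", np.round(np.sort(summary.stationary_median)[::-1], 4))
print("slowest timescale:    %.2f ns (generator: %.2f ns)"
      % (summary.timescales_median[0], -0.1 / np.log(0.96)))
probs = soft_assign(ensemble, dataset.concatenated())
print("frames with p > 0.95: %.1f%%" % (100 * np.mean(probs.max(axis=1) > 0.95)))

gmap = ensemble_gradient(ensemble, dataset, state=1, n_frames=2000, seed=0)
top = np.argsort(-np.abs(gmap.g))[:4]
print("strongest saliency features:", top.tolist())
```

Output:

```
generator stationary: [0.5312 0.2969 0.1719]
estimated (median):   [0.5391 0.2618 0.198 ]
slowest timescale:    2.21 ns (generator: 2.45 ns)
frames with p > 0.95: 95.3%
strongest saliency features: [11, 10, 19, 3]
```

The three-model ensemble trained on 20,000 frames recovers the generator's
equilibrium distribution to a few percent and its slowest relaxation time
(−τ/ln 0.96 at the 0.1 ns frame interval) to ~10%; 95% of frames are
assigned to a state with probability above 0.95, i.e. the soft and hard
assignments nearly coincide; and the strongest saliency entries (11, 10,
19, 3, …) fall inside the designated feature block where the generator's
states actually differ — the interpretation layer points at the right
coordinates.

The same pipeline runs from the shell:

```bash
vampens simulate --n-trajectories 4 --frames 5000 --seed 1 --out feats.h5
vampens train --features feats.h5 --states 3 --lag-steps 5 \
              --ensemble 20 --inits 3 --seed 1 --out ens.npz
vampens kinetics --checkpoint ens.npz --features feats.h5 --out kinetics.json
vampens align-across --checkpoint1 ens.npz --checkpoint2 other.npz --out cross.json
vampens run --config run.yaml        # whole pipeline, cached, provenance-stamped
```

For real trajectories, start with
`vampens featurize --topology top.pdb --trajectory traj.xtc --out feats.h5`.

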