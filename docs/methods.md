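# Methods

`vampens` learns ensembles of *soft* Markov state models (MSMs) from
molecular-dynamics feature trajectories, makes the learned states comparable
within and across systems, and explains them. This note documents the models,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Featurization

A frame of an R-residue chain is represented by the upper triangle of its
inter-residue distance matrix with the diagonal and the first two
off-diagonal bands removed, giving F(R) = (R−2)(R−3)/2 features in Å
(R = 42 → 780). Neighbouring-residue distances are nearly constant and carry
no conformational information, hence the excluded bands. Two residue-distance
conventions are supported — minimum over heavy-atom pairs (default) and
Cα–Cα — because both appear in practice; the mode is recorded in every
output and the pair ordering (row-major over i < j, j − i ≥ 3; 0-based in
code, 1-based in reports) is the coordinate system for every downstream
vector. Trajectory ingest goes through `mdtraj` (PDB topology + XTC/DCD,
nm→Å on read); features are stored raw (un-standardized) in HDF5 so they
remain physically interpretable.

## Soft MSMs and the VAMP-E objective

The state-assignment function χ: R^F → Δ^{M−1} is a multilayer perceptron
with a softmax head, so its output is a probability vector by construction.
Training follows the variational approach to Markov processes: with
X = χ(frames at t), Y = χ(frames at t+τ) over time-lagged pairs drawn within
(never across) trajectories, the objective is

  score = tr[ C00⁻¹ C0τ Cττ⁻¹ C0τᵀ ],   C00 = XᵀX/P, C0τ = XᵀY/P, Cττ = YᵀY/P,

the sum of squared singular values of C00^{−1/2} C0τ Cττ^{−1/2}. Evaluated
self-consistently on a pair set, this is the VAMP-E score of the model; its
population limit for an exact M-state decomposition of a reversible chain is
1 + Σᵢ λᵢ², so the constant function contributes exactly 1 and every resolved
slow process λᵢ adds λᵢ². Covariances are *not* mean-removed — the constant
mode is the σ₁ = 1 singular pair.

The score's gradient is derived analytically (no automatic differentiation):
with A = C00⁻¹, B = Cττ⁻¹,

  ∂L/∂C0τ = 2 A C0τ B, ∂L/∂C00 = −A C0τ B C0τᵀ A, ∂L/∂Cττ = −B C0τᵀ A C0τ B,

pushed through the covariance definitions to per-sample gradients and then
through the softmax and hidden layers by hand-written backpropagation.
A Tikhonov term ε·I (default 1e−6) on C00 and Cττ guards near-singular
minibatch covariances.

Protocol (defaults): the pairs are split into N = 20 random 90/10
train/validation partitions; per split, 3 networks are trained from
different initializations by Adam ascent (lr 1e−3, batch 1024, ≤100 epochs,
early stopping on validation VAMP-E with patience 10) and the
highest-validation-score network is retained. The ensemble's *soft
assignment* of a frame is the mean of the permutation-corrected member
probabilities; the *hard assignment* is its argmax with ties resolved to the
lowest state index. Seeds expand from one master seed through
`numpy.random.SeedSequence` spawn keys, so each (split, init) is
reproducible and decorrelated.

Architecture defaults are 4×100 hidden units for full-size (780-feature)
inputs; the synthetic benchmarks use 1×32, which those problems saturate.
The default hidden activation is `tanh`. A self-normalizing (SELU) option is
provided, but a smooth activation is the default deliberately: exact input
gradients are a first-class deliverable of this package, and SELU's
derivative is discontinuous at 0, which contaminates finite-difference
validation of saliency maps and adds kink noise to the maps themselves. On
the benchmark problems the two activations train equally well.

The "physical constraints" (reversibility and entrywise non-negativity of
the learned operator) are enforced at the estimation step, not inside the
network: see next section.

## Kinetics

Soft transition counts C = XᵀY and the reversible maximum-likelihood
transition matrix via the standard self-consistent reweighting iteration on
symmetric fluxes, x_ij ← (c_ij + c_ji)/(c_i/x_i· + c_j/x_j·), iterated to
max-change < 1e−12 (cap 10⁴ iterations). The fixed point is row-stochastic,
non-negative and satisfies detailed balance π_i T_ij = π_j T_ji exactly by
symmetry of x; an unconstrained mode (row-normalized counts) is available.
States with negligible probability mass raise a reducibility error naming
the state.

Derived quantities: equilibrium distribution (dominant left eigenvector);
mean first-passage times from the standard linear solve on the τ-jump chain,
scaled by the lag time (no sub-lag interpolation — the only convention
computable from T(τ)); implied timescales tᵢ = −τ/ln|λᵢ| with real
non-positive eigenvalues flagged as NaN rather than erroring; and the
Chapman–Kolmogorov comparison of T(τ)^k against directly estimated T(kτ).
Ensemble error bars use the median and the band of half-width equal to the
95th percentile of |value − median| over the members (linear percentile
interpolation).

## State alignment

**Within a system** the N retained networks order their output states
arbitrarily. Each state of each model is summarized by its ξ̄ matrix — the
probability-weighted (default; hard-membership optional) mean feature vector
over the training frames — and the ensemble is aligned by constrained
k-means over the ξ̄s: centers initialize from one model's matrices
(seed-controlled choice), each model's states are assigned greedily to
*distinct* clusters by globally sorting all (state, center) distances
ascending (ties: lower state index, then lower cluster index), and centers
are recomputed as member means until the assignment repeats. Because the
greedy step does not guarantee a monotone objective, assignment fingerprints
are tracked and a cycle or the iteration cap (100) terminates the loop with
`converged=False`; a genuine fixed point sets `converged=True`.

**Across two systems** each common state m is characterized by the uniform
empirical distribution ρ_m of its N ξ̄ matrices (Dirac atoms in feature
space). The cost of aligning state m of one system with state l of another
is the Wasserstein-1 distance W₁(ρ_m, ρ'_l) under the Euclidean ground
metric, solved as the optimal-transport linear program (HiGHS). The optimal
bijection of the smaller state set into the larger minimizes the summed cost
(Hungarian algorithm); when the first system has more states the matrix is
transposed internally and the orientation recorded. A pair counts as
*matched* only if its cost is below the threshold T_e (default 6, in the Å
units of the feature space) — an empirical cutoff separating genuinely
shared states from forced pairings; reports always include raw costs so
users can re-threshold.

## Saliency gradients

For state m, g_m is the ensemble mean of the exact gradient of each model's
(permutation-corrected) output probability for m with respect to the *raw*
input distances, chain-ruled through each model's standardizer so the units
are 1/Å. The sign convention is fixed: positive means the state's
probability rises when that inter-residue distance grows. g_m is averaged
over 10,000 frames sampled uniformly without replacement (seed-controlled);
a state-conditioned variant restricts the sample to frames hard-assigned to
a chosen state. Because the outputs sum to one, Σ_m g_m = 0 for every frame
— an identity the tests enforce at 1e−8. For display g is arranged into the
R×R matrix (excluded bands neutral, diverging palette with symmetric limits
at the 99th percentile of |g|), and per-residue profiles sum each residue's
kept-pair entries, signed or absolute (absolute is the default importance
profile; both are provided since either convention is defensible).

## Free-energy landscapes

tICA solves C(τ) v = λ C(0) v with symmetrized (reversible) covariance
estimates on mean-free features; the top two eigenvectors define the
projection (lag defaults to the MSM lag). The free-energy surface is
F = −ln p̂ in kT units, with p̂ a Gaussian KDE (Scott's rule bandwidth,
scalar multiplier configurable) fitted on a 10% random subsample of the
projected frames, evaluated on a 100×100 grid over the data extent padded
5%, and shifted so min F = 0.

## Synthetic benchmark

The generator emits frames from a hidden Markov chain over K states with
state-specific feature means and truncated-at-zero Gaussian noise, starting
at stationarity (so empirical frequencies estimate π without burn-in).
Emissions live directly in feature space — no pseudo-3D coordinates — for
speed and exact control; base "distances" grow with sequence separation
(6 + 1.2·(j−i) Å) to stay distance-like.

The canonical fixture: K = 3 states on R = 12 pseudo-residues (45 features),
transition matrix with eigenvalues exactly (1, 0.96, 0.92) and stationary
vector (0.53125, 0.296875, 0.171875), state offsets of +3 Å on 8 features of
a 15-feature block B (pairs within the first 8 residues), noise σ = 1 Å.
These conditions put the Bayes error near 1e−5 — separable, but only after
the network finds the block. The closed-loop benchmark uses 10 trajectories
× 10,000 frames, lag 5 steps (0.5 ns at the 0.1 ns frame interval) and a
5-model ensemble (3 inits per split) — sizes chosen so the full loop runs on
a laptop-class single core in about a minute and a half while leaving wide
statistical margins on the ±0.05 equilibrium and ±20% timescale targets.
The two-system fixture copies system 1, perturbs the non-shared states'
block features by +4 Å (Wasserstein cost ≈ 4·√15 ≈ 15.5, safely above
T_e = 6, while shared-state costs are sampling noise ≪ 1) and relabels
states by a recorded permutation.

What passing these benchmarks shows: the estimators recover a known
generator through the entire pipeline — training, alignment, kinetics,
saliency, FES — at the stated tolerances. What it does not show: behaviour
on real MD data, where emissions are neither Gaussian nor state-conditionally
independent, metastability is imperfect, the featurization is 780-dimensional
and strongly correlated, and lag-time choice is a genuine modelling decision
(the implied-timescale and Chapman–Kolmogorov tools exist precisely for
that). The generator is not an attempt to emulate any particular peptide's
conformational distribution.

## Degenerate inputs and numerical guards

Fewer pairs than states → singular-covariance error with a regularization
hint; unpopulated state in ξ̄ or count estimation → error naming the model
and state; non-finite training loss → abort with seed and epoch; rank-
deficient tICA covariance → regularized with a warning; KDE subsample
< 100 points → error; datasets smaller than the requested gradient sample →
use all frames with a warning; asymmetric matrices in `vectorize` and length
mismatches in `devectorize` → errors reporting the expected shape.

## Known limitations

- No transition-path theory beyond MFPTs, no PCCA coarse-graining, no
  hidden-Markov/GME/GLE variants, no reweighting of biased sampling.
- Pairwise (two-system) alignment only; no joint alignment of ≥3 systems
  and no fractional state matching.
- The pair split is over pairs, not trajectories (the standard protocol);
  a trajectory-block split for leakage-sensitive uses is a config switch.
- Training runs on CPU with hand-written backprop; it is sized for feature
  vectors (hundreds of dimensions), not raw-coordinate deep networks.
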