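"""Inter-residue distance featurization of peptide conformations.

A conformation of an R-residue chain is represented by the upper-triangular
part of its R x R inter-residue distance matrix, excluding the diagonal and
the first two off-diagonal bands (distances to sequence neighbours i+1 and
i+2 carry almost no conformational signal).  That leaves one feature per
residue pair (i, j) with j - i >= 3, i.e. F(R) = (R - 2)(R - 3) / 2 features;
for a 42-residue peptide this is the familiar 780-dimensional vector.

Distances are reported in Angstrom.  Two residue-pair distance conventions
are supported: the minimum over heavy-atom pairs of the two residues, or the
C-alpha to C-alpha distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "DistanceMode",
    "ResidueChain",
    "TrajectoryDataset",
    "EXCLUDED",
    "feature_count",
    "pair_index",
    "compute_distance_features",
    "featurize_mdtraj",
    "vectorize",
    "devectorize",
    "save_feature_dataset",
    "load_feature_dataset",
]

#: Sentinel stored on the diagonal and first two off-diagonal bands of the
#: matrix arrangement, which carry no feature.
EXCLUDED: float = np.nan

NM_TO_ANGSTROM = 10.0


class DistanceMode(str, Enum):
    """How the distance between two residues is measured."""

    MIN_HEAVY_ATOM = "min-heavy-atom"
    C_ALPHA = "c-alpha"


def feature_count(n_residues: int) -> int:
    """Number of retained residue pairs, (R-2)(R-3)/2, for R >= 4."""
    if n_residues < 4:
        return 0
    return (n_residues - 2) * (n_residues - 3) // 2


def pair_index(n_residues: int) -> np.ndarray:
    """Ordered (F, 2) array of 0-based residue pairs (i, j), j - i >= 3.

    Row-major over the upper triangle: (0,3), (0,4), ..., (1,4), ...
    This ordering defines the coordinate system of every feature vector,
    gradient vector and matrix arrangement in the package.
    """
    pairs = [
        (i, j)
        for i in range(n_residues)
        for j in range(i + 3, n_residues)
    ]
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


@dataclass
class ResidueChain:
    """Residue -> atom-index bookkeeping for featurization.

    Parameters
    ----------
    atom_groups
        One sequence of atom indices per residue.  In ``MIN_HEAVY_ATOM``
        mode these are the residue's heavy atoms; in ``C_ALPHA`` mode each
        group must contain exactly one atom (the C-alpha).
    mode
        Distance convention.
    """

    atom_groups: Sequence[Sequence[int]]
    mode: DistanceMode = DistanceMode.MIN_HEAVY_ATOM

    def __post_init__(self) -> None:
        self.mode = DistanceMode(self.mode)
        if self.n_residues < 4:
            raise ValueError(
                f"need at least 4 residues for any feature, got {self.n_residues}"
            )
        for r, group in enumerate(self.atom_groups):
            if len(group) == 0:
                raise ValueError(f"residue {r + 1} has no atoms in mode {self.mode.value}")
            if self.mode is DistanceMode.C_ALPHA and len(group) != 1:
                raise ValueError(
                    f"residue {r + 1}: c-alpha mode needs exactly one atom per residue"
                )

    @property
    def n_residues(self) -> int:
        return len(self.atom_groups)

    @property
    def n_features(self) -> int:
        return feature_count(self.n_residues)


def compute_distance_features(
    coordinates: np.ndarray, chain: ResidueChain
) -> np.ndarray:
    """Featurize one frame or a stack of frames.

    Parameters
    ----------
    coordinates
        ``(n_atoms, 3)`` or ``(n_frames, n_atoms, 3)`` positions in Angstrom.
    chain
        Residue definition and distance mode.

    Returns
    -------
    ``(F,)`` or ``(n_frames, F)`` feature array, F = (R-2)(R-3)/2, in the
    ``pair_index`` ordering.
    """
    coords = np.asarray(coordinates, dtype=np.float64)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    if coords.ndim != 3 or coords.shape[-1] != 3:
        raise ValueError("coordinates must have shape (n_atoms, 3) or (n_frames, n_atoms, 3)")
    n_atoms = coords.shape[1]
    for r, group in enumerate(chain.atom_groups):
        if max(group) >= n_atoms:
            raise ValueError(
                f"residue {r + 1} references atom {max(group)} but only "
                f"{n_atoms} atoms were given"
            )

    pairs = pair_index(chain.n_residues)
    out = np.empty((coords.shape[0], len(pairs)), dtype=np.float64)
    for k, (i, j) in enumerate(pairs):
        gi = np.asarray(chain.atom_groups[i], dtype=np.int64)
        gj = np.asarray(chain.atom_groups[j], dtype=np.int64)
        # (n_frames, |gi|, |gj|) pairwise distances, reduced by min
        diff = coords[:, gi, None, :] - coords[:, None, gj, :]
        d = np.sqrt(np.sum(diff * diff, axis=-1))
        out[:, k] = d.min(axis=(1, 2))
    return out[0] if single else out


def featurize_mdtraj(traj, mode: DistanceMode | str = DistanceMode.MIN_HEAVY_ATOM,
                     chain_id: str | int | None = None) -> np.ndarray:
    """Featurize an ``mdtraj.Trajectory`` (coordinates are converted nm -> A).

    ``chain_id`` optionally restricts the residue selection to one chain
    (by index or chain id).  Water/ions are excluded automatically (only
    protein residues are used).
    """
    mode = DistanceMode(mode)
    top = traj.topology
    residues = [r for r in top.residues if r.is_protein]
    if chain_id is not None:
        residues = [
            r for r in residues
            if r.chain.index == chain_id or getattr(r.chain, "chain_id", None) == chain_id
        ]
    if len(residues) < 4:
        raise ValueError(f"selection yields {len(residues)} protein residues; need >= 4")
    groups: list[list[int]] = []
    for r in residues:
        if mode is DistanceMode.C_ALPHA:
            ca = [a.index for a in r.atoms if a.name == "CA"]
            if not ca:
                raise ValueError(f"residue {r} has no CA atom")
            groups.append(ca)
        else:
            heavy = [a.index for a in r.atoms if a.element is not None
                     and a.element.symbol != "H"]
            if not heavy:
                raise ValueError(f"residue {r} has no heavy atoms")
            groups.append(heavy)
    chain = ResidueChain(groups, mode=mode)
    return compute_distance_features(traj.xyz * NM_TO_ANGSTROM, chain)


def _infer_r(n_features: int) -> int:
    # invert F = (R-2)(R-3)/2
    r = int(round((5 + np.sqrt(1 + 8 * n_features)) / 2))
    if feature_count(r) != n_features:
        raise ValueError(f"{n_features} is not a valid feature count for any residue number")
    return r


def vectorize(matrix: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Extract the feature vector from an R x R symmetric distance matrix.

    Entries on the excluded bands (|i - j| < 3) are ignored; the rest must be
    symmetric within ``atol``.
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("expected a square matrix")
    r = m.shape[0]
    pairs = pair_index(r)
    upper = m[pairs[:, 0], pairs[:, 1]]
    lower = m[pairs[:, 1], pairs[:, 0]]
    if not np.allclose(upper, lower, atol=atol, rtol=0.0, equal_nan=True):
        raise ValueError("matrix is asymmetric beyond tolerance on kept entries")
    return upper.copy()


def devectorize(v: np.ndarray, n_residues: int | None = None) -> np.ndarray:
    """Arrange a feature vector back into its R x R matrix form.

    The diagonal and the first two off-diagonal bands are set to the
    ``EXCLUDED`` sentinel (NaN); all kept entries are mirrored symmetrically.
    """
    v = np.asarray(v, dtype=np.float64).ravel()
    r = _infer_r(len(v)) if n_residues is None else int(n_residues)
    expected = feature_count(r)
    if len(v) != expected:
        raise ValueError(
            f"feature vector of length {len(v)} does not match R={r} "
            f"(expected {expected})"
        )
    m = np.full((r, r), EXCLUDED, dtype=np.float64)
    pairs = pair_index(r)
    m[pairs[:, 0], pairs[:, 1]] = v
    m[pairs[:, 1], pairs[:, 0]] = v
    return m


@dataclass
class TrajectoryDataset:
    """A list of per-trajectory feature arrays sharing one pair ordering.

    Parameters
    ----------
    trajectories
        Non-empty ``(L_t, F)`` float arrays, one per trajectory.
    frame_interval
        Physical time between saved frames (ns).
    mode
        Distance convention used at featurization time.
    labels
        Optional provenance label per trajectory.
    """

    trajectories: list[np.ndarray]
    frame_interval: float = 0.1
    mode: DistanceMode = DistanceMode.MIN_HEAVY_ATOM
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mode = DistanceMode(self.mode)
        self.trajectories = [np.asarray(t, dtype=np.float64) for t in self.trajectories]
        if not self.trajectories:
            raise ValueError("dataset needs at least one trajectory")
        dims = {t.shape[1] for t in self.trajectories}
        if any(t.ndim != 2 or t.shape[0] == 0 for t in self.trajectories):
            raise ValueError("every trajectory must be a non-empty (L, F) array")
        if len(dims) != 1:
            raise ValueError(f"trajectories disagree on feature dimension: {sorted(dims)}")
        if not self.labels:
            self.labels = [f"traj_{i:03d}" for i in range(len(self.trajectories))]

    @property
    def n_features(self) -> int:
        return self.trajectories[0].shape[1]

    @property
    def n_residues(self) -> int:
        return _infer_r(self.n_features)

    @property
    def n_frames(self) -> int:
        return int(sum(t.shape[0] for t in self.trajectories))

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.trajectories, axis=0)


def save_feature_dataset(path, dataset: TrajectoryDataset) -> None:
    """Write features to HDF5: one dataset per trajectory + pair_index table."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["mode"] = dataset.mode.value
        h5.attrs["units"] = "angstrom"
        h5.attrs["frame_interval"] = dataset.frame_interval
        h5.create_dataset("pair_index", data=pair_index(dataset.n_residues))
        grp = h5.create_group("trajectories")
        for label, t in zip(dataset.labels, dataset.trajectories):
            grp.create_dataset(label, data=t)


def load_feature_dataset(path) -> TrajectoryDataset:
    import h5py

    with h5py.File(path, "r") as h5:
        labels = sorted(h5["trajectories"].keys())
        trajs = [np.asarray(h5["trajectories"][k]) for k in labels]
        return TrajectoryDataset(
            trajectories=trajs,
            frame_interval=float(h5.attrs["frame_interval"]),
            mode=DistanceMode(h5.attrs["mode"]),
            labels=labels,
        )
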