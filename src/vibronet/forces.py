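"""Force-distribution analysis (FDA) on an elastic-network potential.

Pairwise interactions are harmonic springs between residues within a cutoff
of a reference frame: the signed scalar force along the pair axis is
F_ij(t) = −k (r_ij(t) − r_ij⁰), negative when the pair is stretched (the
force on each member points toward the other).  Punctual stress condenses the
pair forces to residues — the sum over incident pairs of the magnitude of the
time-mean force — and state-difference maps rank the residues whose stress
changes most between two conditions (e.g. inactive versus activated states).
Using an elastic network instead of a full force field keeps every quantity
here verifiable against closed-form references; the trade-offs are discussed
in the package's methods notes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .modes import PCModel, pca_matrix
from .trajectory import Trajectory

__all__ = [
    "ElasticNetwork",
    "build_elastic_network",
    "PairwiseForceSet",
    "pairwise_forces",
    "StressProfile",
    "punctual_stress",
    "stress_difference",
    "force_pca",
]


@dataclass
class ElasticNetwork:
    """Springs between residue pairs of a reference structure."""

    pairs: np.ndarray  # (n_pairs, 2) int, i < j
    rest_lengths: np.ndarray  # (n_pairs,)
    spring_constant: float
    cutoff: float


def build_elastic_network(
    reference: np.ndarray, cutoff: float = 10.0, spring_constant: float = 1.0
) -> ElasticNetwork:
    """Define springs between all atom pairs within ``cutoff`` Å of the
    reference frame, with rest lengths equal to the reference distances."""
    if spring_constant <= 0:
        raise ValueError("spring constant must be positive")
    ref = np.asarray(reference, dtype=float)
    n = ref.shape[0]
    d = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    mask = d[iu, ju] <= cutoff
    pairs = np.stack([iu[mask], ju[mask]], axis=1)
    rest = d[iu, ju][mask]
    if (rest == 0).any():
        raise ValueError("coincident atoms in reference (pair distance 0)")
    return ElasticNetwork(
        pairs=pairs, rest_lengths=rest, spring_constant=spring_constant, cutoff=cutoff
    )


@dataclass
class PairwiseForceSet:
    """Signed scalar pair forces along the pair axes, per frame.

    ``forces`` has shape (n_frames, n_pairs); the scalar is the projection of
    the force acting on the first pair member onto the unit vector pointing
    from the second member to the first, so the vector forces on the two
    members are exact opposites (Newton's third law).
    """

    network: ElasticNetwork
    forces: np.ndarray
    resids: np.ndarray
    dt: float

    @property
    def n_pairs(self) -> int:
        return self.network.pairs.shape[0]

    def vector_forces(self, traj: Trajectory, frame: int) -> np.ndarray:
        """Per-atom total force vectors for one frame (n_atoms, 3)."""
        coords = traj.coords[frame]
        i = self.network.pairs[:, 0]
        j = self.network.pairs[:, 1]
        rij = coords[i] - coords[j]
        u = rij / np.linalg.norm(rij, axis=1, keepdims=True)
        f = self.forces[frame][:, None] * u
        out = np.zeros_like(coords)
        np.add.at(out, i, f)
        np.add.at(out, j, -f)
        return out


def pairwise_forces(traj: Trajectory, network: ElasticNetwork) -> PairwiseForceSet:
    """Per-frame signed scalar spring forces: F_p(t) = −k (r_p(t) − r_p⁰)."""
    i = network.pairs[:, 0]
    j = network.pairs[:, 1]
    d = np.linalg.norm(traj.coords[:, i] - traj.coords[:, j], axis=-1)  # (T, P)
    if (d == 0).any():
        raise ValueError("pair distance 0 encountered; force direction undefined")
    forces = -network.spring_constant * (d - network.rest_lengths[None, :])
    return PairwiseForceSet(
        network=network,
        forces=forces,
        resids=np.asarray(traj.atoms["resid"], dtype=int),
        dt=traj.dt,
    )


@dataclass
class StressProfile:
    """Per-residue punctual stress: Σ over incident pairs of |mean force|."""

    resids: np.ndarray
    stress: np.ndarray
    state: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"resid": self.resids, "stress": self.stress})


def punctual_stress(forces: PairwiseForceSet, state: str = "") -> StressProfile:
    """Condense pair forces to residues.

    Each pair contributes the magnitude of its time-mean scalar force to both
    member residues, so the profile total equals twice the summed pair
    magnitudes.
    """
    mean_abs = np.abs(forces.forces.mean(axis=0))
    resids = forces.resids
    uniq = np.unique(resids)
    stress = np.zeros(len(uniq))
    pos = {r: k for k, r in enumerate(uniq)}
    for (i, j), f in zip(forces.network.pairs, mean_abs):
        stress[pos[resids[i]]] += f
        stress[pos[resids[j]]] += f
    return StressProfile(resids=uniq, stress=stress, state=state)


def stress_difference(profile_a: StressProfile, profile_b: StressProfile) -> pd.DataFrame:
    """Signed per-residue stress change b − a, ranked by |change|."""
    if not np.array_equal(profile_a.resids, profile_b.resids):
        only_a = sorted(set(profile_a.resids) - set(profile_b.resids))
        only_b = sorted(set(profile_b.resids) - set(profile_a.resids))
        raise ValueError(
            f"residue sets differ (only in a: {only_a}; only in b: {only_b})"
        )
    diff = profile_b.stress - profile_a.stress
    df = pd.DataFrame({"resid": profile_a.resids, "delta_stress": diff})
    df["rank"] = (-df["delta_stress"].abs()).rank(method="first").astype(int)
    return df.sort_values("rank", ignore_index=True)


def force_pca(forces: PairwiseForceSet) -> PCModel:
    """PCA over pair-force space: which pair combinations co-fluctuate.

    Constant forces yield zero eigenvalues (warned); the eigenvalue sum equals
    the total pair-force variance.
    """
    f = forces.forces
    if f.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if np.allclose(f.var(axis=0), 0.0):
        warnings.warn("pair forces are constant; all eigenvalues are zero", stacklevel=2)
    return pca_matrix(f, dt=forces.dt)
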