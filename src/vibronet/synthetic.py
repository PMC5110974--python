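"""Synthetic trajectories, structures and alignments with planted ground truth.

Every generator returns its artifact together with a :class:`PlantedTruth`
that records exactly what was planted (mode frequencies and shapes, H-bond
switching rates, fragment-global coupling strengths, covarying column pairs,
hinge residues), so each downstream analysis stage can be scored without
re-deriving parameters.  All generators are bit-reproducible given the spec
and seed.

Defaults emulate the statistical structure of the receptor trajectories and
alignments the pipeline targets: frames saved every 100 fs; low-frequency
harmonic modes in the tens of cm⁻¹; hydrogen bonds switching as a two-state
Markov (telegraph) process; four-residue local fragments whose conformer
toggles couple to a slow global collective coordinate; and class-A-receptor-
like alignments with conserved columns, redundant sequence clusters and
planted covarying pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .constants import omega_to_wavenumber, wavenumber_to_omega
from .coupling import StructuralAlphabet, default_alphabet
from .coevolution import N_AA, WeightedMSA
from .trajectory import Trajectory

__all__ = [
    "SyntheticSpec",
    "PlantedTruth",
    "generate_harmonic_trajectory",
    "stiffness_for_frequencies",
    "chain_stiffness_1d",
    "generate_hbond_telegraph",
    "generate_fragment_switch_trajectory",
    "generate_msa",
    "generate_two_domain_elastic",
]


@dataclass
class SyntheticSpec:
    """Shared knobs of the generators.

    ``dt`` defaults to 100 fs, the save interval of the production
    trajectories this pipeline is designed for; ``velocity_scale`` sets the
    temperature-like magnitude of mode velocities (Å/fs).
    """

    n_frames: int = 1000
    dt: float = 100.0
    n_atoms: int = 3
    n_residues: int = 40
    n_sequences: int = 500
    n_columns: int = 100
    velocity_scale: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be ≥ 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator.

    Frequencies are wavenumbers in cm⁻¹; coupling strengths lie in [0, 1];
    the seed fully determines the generated artifact.  ``extras`` carries
    generator-specific material (hidden state sequences, analytic values,
    cluster labels) that oracles may need.
    """

    mode_frequencies: list[float] = field(default_factory=list)
    mode_vectors: np.ndarray | None = None
    hbond_rates: tuple[float, float] | None = None
    coupled_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    hinge_residues: list[int] = field(default_factory=list)
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if any(f <= 0 for f in self.mode_frequencies):
            raise ValueError("planted frequencies must be positive")
        if any(not (0.0 <= c <= 1.0) for _, _, c in self.coupled_pairs):
            raise ValueError("coupling strengths must be in [0, 1]")

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["mode_vectors"] = (
            None if self.mode_vectors is None else np.asarray(self.mode_vectors).tolist()
        )
        data["extras"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.extras.items()
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1, default=float)


# ---------------------------------------------------------------------------
# harmonic trajectories
# ---------------------------------------------------------------------------

_FREQ_TOL = 1e-10  # ω² below this (rad/fs)² counts as a free (zero) mode


def generate_harmonic_trajectory(
    spec: SyntheticSpec,
    stiffness: np.ndarray,
    masses: np.ndarray,
    origin: np.ndarray | None = None,
    free_mode_velocity_scale: float | None = None,
) -> tuple[Trajectory, PlantedTruth]:
    """Exact normal-mode trajectory of a harmonic system.

    ``stiffness`` is the symmetric positive-semidefinite (3N, 3N) matrix of a
    potential ½ xᵀKx (amu/fs² units) and ``masses`` the per-atom masses
    (amu).  Positions and velocities are closed-form superpositions of the
    analytic eigenmodes with seeded random phases — there is no integrator,
    so total energy is conserved to machine precision and the planted
    spectrum is exact.  Zero-stiffness (free) modes drift at constant seeded
    velocities of scale ``free_mode_velocity_scale`` (default: the spec's
    velocity scale; pass 0 to freeze unsprung degrees of freedom, e.g. for
    clean spectral-recovery experiments).  Frequencies are reported as
    wavenumbers ν̃ = ω/(2πc).
    """
    masses = np.asarray(masses, dtype=float)
    if (masses <= 0).any():
        raise ValueError("masses must be positive")
    n_atoms = len(masses)
    n_dof = 3 * n_atoms
    K = np.asarray(stiffness, dtype=float)
    if K.shape != (n_dof, n_dof):
        raise ValueError(f"stiffness must be ({n_dof}, {n_dof}) for {n_atoms} atoms")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("stiffness matrix must be symmetric")
    m_dof = np.repeat(masses, 3)
    dyn = K / np.sqrt(np.outer(m_dof, m_dof))
    omega2, modes = np.linalg.eigh((dyn + dyn.T) / 2.0)
    if omega2.min() < -1e-8 * max(abs(omega2).max(), 1.0):
        raise ValueError("stiffness matrix has a negative eigenvalue; not PSD")
    omega2 = np.clip(omega2, 0.0, None)
    finite = omega2 > _FREQ_TOL
    omega = np.sqrt(omega2)

    rng = spec.rng()
    phases = rng.uniform(0.0, 2.0 * np.pi, n_dof)
    free_scale = (
        spec.velocity_scale
        if free_mode_velocity_scale is None
        else free_mode_velocity_scale
    )
    free_velocities = rng.normal(0.0, 1.0, n_dof) * free_scale

    t = np.arange(spec.n_frames) * spec.dt  # fs
    inv_sqrt_m = 1.0 / np.sqrt(m_dof)
    x0 = (
        np.zeros((n_atoms, 3))
        if origin is None
        else np.asarray(origin, dtype=float)
    ).reshape(-1)

    q = np.zeros((spec.n_frames, n_dof))
    qdot = np.zeros((spec.n_frames, n_dof))
    # oscillatory modes: velocity amplitude = velocity_scale for every mode
    for j in np.nonzero(finite)[0]:
        a = spec.velocity_scale / omega[j]
        q[:, j] = a * np.cos(omega[j] * t + phases[j])
        qdot[:, j] = -a * omega[j] * np.sin(omega[j] * t + phases[j])
    for j in np.nonzero(~finite)[0]:
        q[:, j] = free_velocities[j] * t
        qdot[:, j] = free_velocities[j]

    disp = (modes @ q.T).T * inv_sqrt_m[None, :]
    vel = (modes @ qdot.T).T * inv_sqrt_m[None, :]
    coords = (x0[None, :] + disp).reshape(spec.n_frames, n_atoms, 3)
    velocities = vel.reshape(spec.n_frames, n_atoms, 3)

    traj = Trajectory.from_arrays(
        coords=coords, dt=spec.dt, velocities=velocities, masses=list(masses)
    )
    freqs = [omega_to_wavenumber(w) for w in omega[finite]]
    # analytic per-mode energies, constant in time
    energies = 0.5 * spec.velocity_scale**2 * np.ones(int(finite.sum()))
    truth = PlantedTruth(
        mode_frequencies=sorted(freqs),
        mode_vectors=(inv_sqrt_m[:, None] * modes[:, finite]).T,
        seed=spec.seed,
        extras={
            "omega_rad_per_fs": omega[finite].tolist(),
            "mode_energies": energies.tolist(),
            "n_free_modes": int((~finite).sum()),
        },
    )
    return traj, truth


def stiffness_for_frequencies(
    frequencies_cm: list[float], masses: np.ndarray
) -> np.ndarray:
    """Stiffness matrix whose finite eigenfrequencies are the given
    wavenumbers: one spring per frequency, along x of successive atoms."""
    masses = np.asarray(masses, dtype=float)
    if len(frequencies_cm) > len(masses):
        raise ValueError("need at least one atom per planted frequency")
    n_dof = 3 * len(masses)
    K = np.zeros((n_dof, n_dof))
    for i, nu in enumerate(frequencies_cm):
        omega = wavenumber_to_omega(nu)
        K[3 * i, 3 * i] = masses[i] * omega**2
    return K


def chain_stiffness_1d(n_atoms: int, k: float) -> np.ndarray:
    """Free-free nearest-neighbour spring chain along x (3N dof layout)."""
    n_dof = 3 * n_atoms
    K = np.zeros((n_dof, n_dof))
    for i in range(n_atoms - 1):
        a, b = 3 * i, 3 * (i + 1)
        K[a, a] += k
        K[b, b] += k
        K[a, b] -= k
        K[b, a] -= k
    return K


# ---------------------------------------------------------------------------
# telegraph hydrogen bonds
# ---------------------------------------------------------------------------

_ON_GEOMETRY = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]]
)  # D, H, A: linear, D–A 2.9 Å, H···A 1.9 Å → satisfies the criterion
_OFF_GEOMETRY = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [5.0, 0.0, 0.0]]
)  # D–A 5.0 Å → violates the distance criteria


def generate_hbond_telegraph(
    spec: SyntheticSpec,
    k_on: float,
    k_off: float,
    n_bonds: int = 1,
) -> tuple[Trajectory, PlantedTruth]:
    """Hydrogen bonds switching as independent two-state Markov chains.

    Each bond is a donor/hydrogen/acceptor triple whose geometry satisfies
    the standard geometric criterion exactly in the "on" state and violates
    the distance criteria in the "off" state.  States evolve as the exact
    skeleton of the continuous-time two-state chain sampled every dt, so the
    existence autocorrelation is exactly p + (1−p)·exp(−(k_on+k_off)τ)
    regardless of the sampling interval.  The nominal per-step probabilities
    k·dt are still rejected above 1 and warned above 0.1 (coarse sampling
    relative to the kinetics); initial states draw from the stationary
    distribution p = k_on/(k_on+k_off).
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be positive")
    if k_on * spec.dt > 1 or k_off * spec.dt > 1:
        raise ValueError("rate × dt exceeds 1: per-step switch probability invalid")
    if max(k_on, k_off) * spec.dt > 0.1:
        warnings.warn(
            "rate × dt above 0.1: frames sample the switching kinetics coarsely",
            stacklevel=2,
        )
    rng = spec.rng()
    k_sum = k_on + k_off
    p_stat = k_on / k_sum
    decay = np.exp(-k_sum * spec.dt)
    # exact CTMC skeleton transition probabilities over one frame
    p_switch_off = (k_off / k_sum) * (1.0 - decay)  # from on
    p_switch_on = (k_on / k_sum) * (1.0 - decay)  # from off
    T = spec.n_frames
    states = np.empty((n_bonds, T), dtype=int)
    states[:, 0] = rng.random(n_bonds) < p_stat
    u = rng.random((n_bonds, T - 1))
    for t in range(1, T):
        prev = states[:, t - 1]
        switch = np.where(prev == 1, u[:, t - 1] < p_switch_off, u[:, t - 1] < p_switch_on)
        states[:, t] = np.where(switch, 1 - prev, prev)

    coords = np.empty((T, 3 * n_bonds, 3))
    for b in range(n_bonds):
        offset = np.array([0.0, 20.0 * b, 0.0])
        on = _ON_GEOMETRY + offset
        off = _OFF_GEOMETRY + offset
        sel = states[b][:, None, None].astype(bool)
        coords[:, 3 * b : 3 * b + 3] = np.where(sel, on[None], off[None])
    elements = ["O", "H", "O"] * n_bonds
    resids = [b for b in range(n_bonds) for _ in range(3)]
    traj = Trajectory.from_arrays(coords=coords, dt=spec.dt, elements=elements, resids=resids)
    truth = PlantedTruth(
        hbond_rates=(k_on, k_off),
        seed=spec.seed,
        extras={
            "states": states,
            "stationary_occupancy": p_stat,
            "relaxation_time_fs": 1.0 / (k_on + k_off),
            "donors": [(3 * b, 3 * b + 1) for b in range(n_bonds)],
            "acceptors": [3 * b + 2 for b in range(n_bonds)],
        },
    )
    return traj, truth


# ---------------------------------------------------------------------------
# fragment-switch trajectories (local-global coupling)
# ---------------------------------------------------------------------------


def _aligned_prototype(proto: np.ndarray) -> np.ndarray:
    """Rotate a centered 4-point prototype so atom0→atom3 lies along +x and
    atom0 sits at the origin."""
    p = proto - proto[0]
    v = p[3]
    nv = np.linalg.norm(v)
    ex = v / nv
    # build an orthonormal frame deterministically
    trial = np.array([0.0, 0.0, 1.0])
    if abs(ex @ trial) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    ez = np.cross(ex, trial)
    ez /= np.linalg.norm(ez)
    ey = np.cross(ez, ex)
    R = np.stack([ex, ey, ez])
    return p @ R.T


def _rigid_mode_basis(ref: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body modes of a reference structure."""
    n = ref.shape[0]
    centered = ref - ref.mean(axis=0)
    basis = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        basis.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(centered, e).ravel())
    B = np.stack(basis, axis=1)
    q, r = np.linalg.qr(B)
    keep = np.abs(np.diag(r)) > 1e-10
    return q[:, keep]


def generate_fragment_switch_trajectory(
    spec: SyntheticSpec,
    fragments: list[tuple[int, float]] = ((2, 1.0), (8, 0.5), (33, 0.0)),
    alphabet: StructuralAlphabet | None = None,
    conformer_states: tuple[int, int] = (21, 23),
    global_amplitude: float = 13.0,
    second_mode_amplitude: float = 7.0,
    global_switch_prob: float = 0.02,
    jitter: float = 0.05,
) -> tuple[Trajectory, PlantedTruth]:
    """Cα chain with fragment conformer toggles coupled to a global mode.

    A slow two-state global coordinate g(t) = ±1 displaces one chain half
    along a smooth, rigid-body-free pattern of amplitude
    ``global_amplitude`` (Å).  Each designated four-residue fragment toggles
    between two alphabet prototype geometries (the defaults are a
    mirror-image pair sharing both endpoints, so a toggle moves only the
    fragment interior and never the rest of the chain); the fragment state
    copies sign(g) with probability (1+coupling)/2 and is an independent
    fair coin otherwise.  Gaussian positional jitter (``jitter`` Å) plays
    the role of fast thermal noise.

    A second, independent slow collective mode (a longitudinal compression
    wave of amplitude ``second_mode_amplitude``) is planted so that the two
    largest principal components are both genuinely collective motions —
    without it the second PC would be a fragment toggle and the discretized
    "global" state would carry local information.
    """
    alphabet = alphabet or default_alphabet()
    n_res = spec.n_residues
    frags = [(int(s), float(c)) for s, c in fragments]
    for s, c in frags:
        if not (0 <= s <= n_res - 4):
            raise IndexError(f"fragment start {s} out of chain of {n_res} residues")
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"coupling {c} outside [0, 1]")
    starts = [s for s, _ in frags]
    for a, b in zip(sorted(starts), sorted(starts)[1:]):
        if b - a < 4:
            raise ValueError("designated fragments must not overlap")

    rng = spec.rng()
    T = spec.n_frames

    # slow continuous global coordinates: bounded, sign-symmetric AR(1)
    # processes with correlation time 1/global_switch_prob frames
    rho = float(np.exp(-global_switch_prob))

    def slow_coordinate() -> np.ndarray:
        eta = rng.normal(0.0, 1.0, T)
        x = np.empty(T)
        x[0] = eta[0]
        for t in range(1, T):
            x[t] = rho * x[t - 1] + np.sqrt(1.0 - rho**2) * eta[t]
        return np.tanh(x)

    g = slow_coordinate()
    g2 = slow_coordinate()
    g_sign = np.where(g >= 0, 1, -1)

    # fragment states: follow sign(g) with prob coupling, else independent coin
    frag_states = np.empty((len(frags), T), dtype=int)
    for fi, (_, c) in enumerate(frags):
        follow = rng.random(T) < c
        coin = np.where(rng.random(T) < 0.5, 1, -1)
        frag_states[fi] = np.where(follow, g_sign, coin)

    proto_a = _aligned_prototype(alphabet.prototypes[conformer_states[0]])
    proto_b = _aligned_prototype(alphabet.prototypes[conformer_states[1]])
    if np.linalg.norm(proto_a[3] - proto_b[3]) > 0.5:
        raise ValueError(
            "conformer prototypes must share their endpoints (choose a "
            "mirror-image pair) so that toggling does not drag the chain"
        )

    # baseline chain: sequential walk with every fragment in conformer A
    base = np.zeros((n_res, 3))
    cursor = np.zeros(3)
    frag_at = {s: fi for fi, (s, _) in enumerate(frags)}
    i = 0
    while i < n_res:
        if i in frag_at:
            base[i : i + 4] = cursor + proto_a
            cursor = base[i + 3] + np.array([3.8, 0.0, 0.0])
            i += 4
        else:
            base[i] = cursor
            cursor = cursor + np.array([3.8, 0.0, 0.0])
            i += 1

    # global pattern: a smooth sigmoidal *longitudinal* stretch — the second
    # chain half slides along the chain axis.  Longitudinal displacements of a
    # near-linear chain are orthogonal to every rigid-rotation field, so the
    # least-squares fit cannot absorb the motion; the pattern is additionally
    # projected out of the rigid-body subspace.  The ramp is kept wide and the
    # default fragments sit in its flat regions so fragment geometry is barely
    # distorted by the global state.
    idx = np.arange(n_res)
    center = n_res / 2.0 - 0.5
    ramp = np.tanh((idx - center) / 7.0)
    pattern = np.zeros((n_res, 3))
    pattern[:, 0] = ramp
    R = _rigid_mode_basis(base)

    def orthonormalize(p: np.ndarray) -> np.ndarray:
        v = p.ravel()
        v = v - R @ (R.T @ v)
        return v / np.linalg.norm(v)

    u = orthonormalize(pattern)
    # second collective mode: gentle longitudinal compression wave (even
    # about the chain center, hence orthogonal to the odd step ramp)
    wave = np.zeros((n_res, 3))
    wave[:, 0] = np.cos(2.0 * np.pi * (idx - center) / n_res)
    u2 = orthonormalize(wave)
    u2 = u2 - u * (u @ u2)
    u2 /= np.linalg.norm(u2)

    coords = np.empty((T, n_res, 3))
    for t in range(T):
        chain = base.copy()
        for fi, (s, _) in enumerate(frags):
            if frag_states[fi, t] == -1:
                chain[s : s + 4] = base[s] + proto_b
        disp = g[t] * global_amplitude * u + g2[t] * second_mode_amplitude * u2
        coords[t] = chain + disp.reshape(n_res, 3)
    coords += rng.normal(0.0, jitter, coords.shape)

    traj = Trajectory.from_arrays(
        coords=coords,
        dt=spec.dt,
        elements=["C"] * n_res,
        names=["CA"] * n_res,
        resids=list(range(n_res)),
        resnames=["ALA"] * n_res,
    )
    truth = PlantedTruth(
        mode_vectors=np.stack([u, u2]),
        coupled_pairs=[(s, -1, c) for s, c in frags],
        seed=spec.seed,
        extras={
            "global_coordinate": g,
            "global_states": g_sign,
            "second_mode_coordinate": g2,
            "fragment_states": frag_states,
            "fragment_starts": starts,
            "couplings": [c for _, c in frags],
            "conformer_states": list(conformer_states),
            "global_amplitude": global_amplitude,
        },
    )
    return traj, truth


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------


def generate_msa(
    spec: SyntheticSpec,
    background: np.ndarray | None = None,
    planted_pairs: list[tuple[int, int, float]] = (),
    redundancy: list[tuple[int, int, float]] = (),
) -> tuple[WeightedMSA, PlantedTruth]:
    """Alignment with i.i.d. background columns and planted covarying pairs.

    Unplanted columns draw independently from ``background`` (default
    uniform over the 20 amino acids).  A planted pair (i, j, coupling) draws,
    with probability ``coupling``, a symbol a ~ background for column i and
    the permuted symbol π(a) for column j (a seeded random permutation per
    pair), and with probability 1−coupling the two independently — so the
    joint table is the stated mixture and its analytic MI is recorded in the
    truth.  ``redundancy`` entries (seq_index, n_copies, mutation_rate)
    append near-duplicates of a sequence with i.i.d. per-site mutations.
    """
    if spec.n_columns < 2 or spec.n_sequences < 2:
        raise ValueError("need at least 2 columns and 2 sequences")
    bg = (
        np.full(N_AA, 1.0 / N_AA)
        if background is None
        else np.asarray(background, dtype=float)
    )
    bg = bg / bg.sum()
    used: set[int] = set()
    for i, j, c in planted_pairs:
        if not (0.0 <= c <= 1.0):
            raise ValueError(f"coupling {c} outside [0, 1]")
        if i in used or j in used or i == j:
            raise ValueError("planted pairs must be disjoint")
        used.update((i, j))
        if not (0 <= i < spec.n_columns and 0 <= j < spec.n_columns):
            raise IndexError("planted pair column out of range")

    rng = spec.rng()
    n, C = spec.n_sequences, spec.n_columns
    codes = rng.choice(N_AA, size=(n, C), p=bg).astype(np.int8)

    pair_tables = {}
    for i, j, c in planted_pairs:
        perm = rng.permutation(N_AA)
        a = rng.choice(N_AA, size=n, p=bg)
        coupled = rng.random(n) < c
        b_indep = rng.choice(N_AA, size=n, p=bg)
        b = np.where(coupled, perm[a], b_indep)
        codes[:, i] = a
        codes[:, j] = b
        # joint table: coupled part puts mass bg[a] on (a, perm[a])
        joint = np.zeros((N_AA, N_AA))
        joint[np.arange(N_AA), perm] = c * bg
        joint += (1.0 - c) * np.outer(bg, bg)
        pa = joint.sum(axis=1)
        pb = joint.sum(axis=0)
        nz = joint > 0
        mi = float(
            (joint[nz] * np.log(joint[nz] / (np.outer(pa, pb)[nz]))).sum()
        )
        pair_tables[(i, j)] = {"permutation": perm.tolist(), "analytic_mi": mi}

    ids = [f"seq{k:04d}" for k in range(n)]
    cluster_labels = list(range(n))
    for src, n_copies, mut_rate in redundancy:
        for c_i in range(n_copies):
            copy = codes[src].copy()
            mut = rng.random(C) < mut_rate
            copy[mut] = rng.choice(N_AA, size=int(mut.sum())).astype(np.int8)
            codes = np.vstack([codes, copy[None, :]])
            ids.append(f"seq{src:04d}_dup{c_i}")
            cluster_labels.append(src)

    msa = WeightedMSA(codes=codes, ids=ids)
    truth = PlantedTruth(
        coupled_pairs=[(i, j, c) for i, j, c in planted_pairs],
        seed=spec.seed,
        extras={
            "pair_tables": {f"{i},{j}": v for (i, j), v in pair_tables.items()},
            "cluster_labels": cluster_labels,
            "background": bg.tolist(),
        },
    )
    return msa, truth


# ---------------------------------------------------------------------------
# two-domain elastic structures
# ---------------------------------------------------------------------------


def generate_two_domain_elastic(
    n_res_per_domain: int = 20,
    linker_len: int = 3,
    seed: int = 0,
) -> tuple[Trajectory, PlantedTruth]:
    """Two compact Cα clusters joined by an extended linker.

    Domain residues sit on a jittered cubic lattice (5 Å spacing, dense
    contacts at the usual 10 Å GNM cutoff); the linker is a straight strand
    at 3.8 Å spacing.  The planted hinge is the set of linker residues.
    """
    if n_res_per_domain < 5:
        raise ValueError("domains need at least 5 residues")
    if linker_len < 1:
        raise ValueError("need at least 1 linker residue")
    rng = np.random.default_rng(seed)

    def domain(center: np.ndarray) -> np.ndarray:
        side = int(np.ceil(n_res_per_domain ** (1.0 / 3.0)))
        pts = []
        for i in range(side):
            for j in range(side):
                for k in range(side):
                    pts.append([i, j, k])
                    if len(pts) == n_res_per_domain:
                        break
                else:
                    continue
                break
            else:
                continue
            break
        pts = np.asarray(pts, dtype=float) * 5.0
        pts += rng.normal(0.0, 0.3, pts.shape)
        return pts - pts.mean(axis=0) + center

    linker_span = (linker_len + 1) * 3.8
    half = linker_span / 2.0 + 6.0
    dom_a = domain(np.array([-half, 0.0, 0.0]))
    dom_b = domain(np.array([half, 0.0, 0.0]))
    # attach the linker between the closest faces of the domains
    start = dom_a[np.argmax(dom_a[:, 0])]
    end = dom_b[np.argmin(dom_b[:, 0])]
    ts = np.linspace(0.0, 1.0, linker_len + 2)[1:-1]
    linker = start[None, :] + ts[:, None] * (end - start)[None, :]

    coords = np.vstack([dom_a, linker, dom_b])[None, :, :]
    n_total = coords.shape[1]
    hinge = list(range(n_res_per_domain, n_res_per_domain + linker_len))
    traj = Trajectory.from_arrays(
        coords=coords,
        dt=1.0,
        elements=["C"] * n_total,
        names=["CA"] * n_total,
        resids=list(range(n_total)),
        resnames=["ALA"] * n_total,
    )
    truth = PlantedTruth(hinge_residues=hinge, seed=seed)
    return traj, truth
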