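"""Local structural fluctuations via a 25-state structural alphabet, and
their mutual-information coupling to global collective states.

Local structure is encoded per frame by sliding a four-residue window along
the Cα chain and assigning each fragment the closest of 25 canonical fragment
geometries (minimum superposition RMSD).  Columns of the resulting
state-by-frame alignment are compared with positional mutual information
(natural log); the coupling of a fragment to the global motion is the MI
between its state series and a discretized collective state built from the
top-two PCA projections, normalized by the joint entropy so that identical
series score 1 and independent series 0.

The default alphabet bundled here is synthetic: 25 four-point prototypes on a
5×5 grid of backbone bend angles and dihedrals at 3.8 Å Cα spacing.  Any
25-state alphabet with the same JSON layout (e.g. a published fragment
library) can be substituted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .modes import PCModel
from .trajectory import Trajectory

__all__ = [
    "StructuralAlphabet",
    "default_alphabet",
    "SAEncoding",
    "encode_fragments",
    "mutual_information",
    "entropy",
    "lsf_mi_matrix",
    "discretize_global",
    "CouplingProfile",
    "lsf_gsf_coupling",
    "lsf_network",
]

CHAIN_BREAK_DISTANCE = 4.5  # Å, Cα–Cα


# ---------------------------------------------------------------------------
# structural alphabet
# ---------------------------------------------------------------------------


def _place_fragment(bond: float, theta1: float, theta2: float, phi: float) -> np.ndarray:
    """Four Cα positions from internal coordinates (angles in degrees)."""
    t1, t2, p = np.radians([theta1, theta2, phi])
    a0 = np.zeros(3)
    a1 = np.array([bond, 0.0, 0.0])
    # third atom in the xy-plane, bond angle theta1 at a1
    a2 = a1 + bond * np.array([-np.cos(t1), np.sin(t1), 0.0])
    # fourth atom: bond angle theta2 at a2, dihedral phi about a1→a2
    b1 = a1 - a0
    b2 = a2 - a1
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    d = bond * (
        -np.cos(t2) * b2n + np.sin(t2) * (np.cos(p) * m + np.sin(p) * n)
    )
    a3 = a2 + d
    frag = np.stack([a0, a1, a2, a3])
    return frag - frag.mean(axis=0)


@dataclass
class StructuralAlphabet:
    """Exactly 25 canonical four-residue Cα fragment geometries."""

    prototypes: np.ndarray  # (25, 4, 3), each centered
    labels: list[str]

    def __post_init__(self):
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        if self.prototypes.shape != (25, 4, 3):
            raise ValueError("alphabet must hold exactly 25 four-point prototypes")
        if len(self.labels) != 25:
            raise ValueError("need 25 labels")
        self.prototypes = self.prototypes - self.prototypes.mean(axis=1, keepdims=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "StructuralAlphabet":
        with open(path) as fh:
            data = json.load(fh)
        return cls(prototypes=np.array(data["prototypes"]), labels=list(data["labels"]))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"labels": self.labels, "prototypes": self.prototypes.tolist()},
                fh,
                indent=1,
            )


def default_alphabet(bond: float = 3.8) -> StructuralAlphabet:
    """Synthetic default alphabet: 5 bend angles × 5 dihedrals.

    Bend angles cover tight turns through extended strands (90°–150°), the
    dihedral grid covers both handedness and planar fragments.
    """
    thetas = [90.0, 105.0, 120.0, 135.0, 150.0]
    phis = [-120.0, -60.0, 0.0, 60.0, 120.0]
    protos = []
    labels = []
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXY"
    k = 0
    for th in thetas:
        for ph in phis:
            protos.append(_place_fragment(bond, th, th, ph))
            labels.append(letters[k])
            k += 1
    return StructuralAlphabet(prototypes=np.stack(protos), labels=labels)


# ---------------------------------------------------------------------------
# fragment encoding
# ---------------------------------------------------------------------------


@dataclass
class SAEncoding:
    """State label per (fragment, frame) plus the assignment RMSDs.

    ``states`` holds integer prototype indices of shape
    (n_fragments, n_frames); ``fragment_starts`` maps rows to the first
    residue of each four-residue window.  Fragments spanning a chain break
    are excluded.
    """

    states: np.ndarray
    rmsd: np.ndarray
    fragment_starts: np.ndarray
    labels: list[str]

    @property
    def n_fragments(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def state_letters(self, fragment: int) -> str:
        return "".join(self.labels[s] for s in self.states[fragment])


def _batched_kabsch_rmsd(frags: np.ndarray, protos: np.ndarray) -> np.ndarray:
    """Min-RMSD of each fragment against each prototype (proper rotations).

    frags: (..., 4, 3) centered; protos: (P, 4, 3) centered.
    Returns (..., P).
    """
    lead = frags.shape[:-2]
    X = frags.reshape(-1, 4, 3)
    P = protos.shape[0]
    # cross-covariance H[b, p] = X[b]^T @ protos[p]
    H = np.einsum("bni,pnj->bpij", X, protos)
    U, S, Vt = np.linalg.svd(H)
    detsign = np.sign(np.linalg.det(U) * np.linalg.det(Vt))
    S_corr = S.copy()
    S_corr[..., -1] *= detsign
    x2 = np.einsum("bni,bni->b", X, X)[:, None]
    p2 = np.einsum("pni,pni->p", protos, protos)[None, :]
    msd = (x2 + p2 - 2.0 * S_corr.sum(axis=-1)) / 4.0
    return np.sqrt(np.clip(msd, 0.0, None)).reshape(*lead, P)


def encode_fragments(
    traj: Trajectory | np.ndarray,
    alphabet: StructuralAlphabet | None = None,
    fragment_starts: list[int] | None = None,
) -> SAEncoding:
    """Encode four-residue fragments of a Cα chain into alphabet states.

    ``traj`` is a Cα trajectory (or a bare (F, N, 3) array).  By default every
    window i..i+3 along the chain is encoded; fragments containing a chain
    break (consecutive Cα–Cα above 4.5 Å in any frame) are dropped with a
    warning.  RMSD ties go to the lowest prototype index.
    """
    alphabet = alphabet or default_alphabet()
    coords = traj.coords if isinstance(traj, Trajectory) else np.asarray(traj, dtype=float)
    F, N, _ = coords.shape
    if N < 4:
        raise ValueError("chain must have at least 4 residues")
    starts = list(range(N - 3)) if fragment_starts is None else list(fragment_starts)
    for s in starts:
        if not (0 <= s <= N - 4):
            raise IndexError(f"fragment start {s} out of chain of length {N}")
    # chain-break detection on consecutive distances across all frames
    consec = np.linalg.norm(np.diff(coords, axis=1), axis=-1)  # (F, N-1)
    broken_link = (consec > CHAIN_BREAK_DISTANCE).any(axis=0)
    keep = []
    for s in starts:
        if broken_link[s : s + 3].any():
            warnings.warn(f"fragment {s}..{s + 3} spans a chain break; excluded", stacklevel=2)
        else:
            keep.append(s)
    if not keep:
        raise ValueError("no intact fragment to encode")
    frag = np.stack([coords[:, s : s + 4] for s in keep], axis=1)  # (F, nf, 4, 3)
    frag = frag - frag.mean(axis=2, keepdims=True)
    rmsd = _batched_kabsch_rmsd(frag, alphabet.prototypes)  # (F, nf, 25)
    states = np.argmin(rmsd, axis=-1)  # ties → lowest index via argmin
    best = np.take_along_axis(rmsd, states[..., None], axis=-1)[..., 0]
    return SAEncoding(
        states=states.T,
        rmsd=best.T,
        fragment_starts=np.asarray(keep, dtype=int),
        labels=alphabet.labels,
    )


# ---------------------------------------------------------------------------
# discrete information measures (natural log)
# ---------------------------------------------------------------------------


def entropy(labels: np.ndarray) -> float:
    """Plug-in Shannon entropy (nats) of a discrete label series."""
    _, counts = np.unique(np.asarray(labels), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats): Σ p(x,y) log p(x,y)/(p(x)p(y))."""
    x = np.asarray(x)
    y = np.asarray(y)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = xi.max() + 1
    ny = yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / len(x)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nzx, nzy = np.nonzero(joint)
    vals = joint[nzx, nzy]
    return float((vals * np.log(vals / (px[nzx] * py[nzy]))).sum())


def lsf_mi_matrix(enc: SAEncoding) -> np.ndarray:
    """Positional MI between fragment-state columns; diagonal = entropies."""
    if enc.n_fragments < 2:
        raise ValueError("need at least 2 fragments")
    if enc.n_frames < 10:
        raise ValueError("need at least 10 frames")
    nf = enc.n_fragments
    M = np.zeros((nf, nf))
    for i in range(nf):
        M[i, i] = entropy(enc.states[i])
        for j in range(i + 1, nf):
            M[i, j] = M[j, i] = mutual_information(enc.states[i], enc.states[j])
    return M


# ---------------------------------------------------------------------------
# global states and local-global coupling
# ---------------------------------------------------------------------------


def discretize_global(model: PCModel, n_bins: int = 10) -> np.ndarray:
    """Joint collective state from equal-frequency bins of the top-2 PCs.

    Each projection is binned by its own quantiles; duplicate quantile edges
    (heavily discrete projections) collapse bins with a warning.  Returns an
    integer state per frame.
    """
    if model.n_modes < 2:
        raise ValueError("need at least two PCA modes for the collective state")
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    bins = []
    for k in (0, 1):
        p = model.projections[:, k]
        edges = np.unique(np.quantile(p, np.linspace(0, 1, n_bins + 1)[1:-1]))
        if len(edges) < n_bins - 1:
            warnings.warn(
                f"PC{k + 1} projections are too discrete for {n_bins} bins; "
                f"collapsed to {len(edges) + 1}",
                stacklevel=2,
            )
        bins.append(np.searchsorted(edges, p, side="right"))
    b1, b2 = bins
    return b1 * (b2.max() + 1) + b2


@dataclass
class CouplingProfile:
    """Per-fragment normalized MI against the global collective state.

    nMI = MI(fragment; global) / H(fragment, global) ∈ [0, 1]; zero joint
    entropy defines nMI = 0.  ``bias`` optionally holds a shuffled-replicate
    estimate of the finite-sample nMI floor.
    """

    fragment_starts: np.ndarray
    nmi: np.ndarray
    bias: np.ndarray | None = None


def _nmi(x: np.ndarray, y: np.ndarray, normalization: str) -> float:
    mi = mutual_information(x, y)
    hx = entropy(x)
    hy = entropy(y)
    h_joint = hx + hy - mi
    if normalization == "joint":
        return mi / h_joint if h_joint > 0 else 0.0
    if normalization == "min":
        m = min(hx, hy)
        return mi / m if m > 0 else 0.0
    raise ValueError("normalization must be 'joint' or 'min'")


def lsf_gsf_coupling(
    enc: SAEncoding,
    global_states: np.ndarray,
    normalization: str = "joint",
    n_shuffles: int = 0,
    rng: np.random.Generator | None = None,
) -> CouplingProfile:
    """Normalized MI between each fragment-state series and the global state.

    ``n_shuffles`` > 0 additionally estimates the finite-sample bias by
    shuffling the global series (the estimate is reported, not subtracted).
    """
    g = np.asarray(global_states)
    if len(g) != enc.n_frames:
        raise ValueError("global state series must match the encoding's frame count")
    nmi = np.array([_nmi(enc.states[i], g, normalization) for i in range(enc.n_fragments)])
    bias = None
    if n_shuffles > 0:
        rng = rng or np.random.default_rng()
        bias = np.zeros(enc.n_fragments)
        for _ in range(n_shuffles):
            gs = rng.permutation(g)
            bias += np.array(
                [_nmi(enc.states[i], gs, normalization) for i in range(enc.n_fragments)]
            )
        bias /= n_shuffles
    return CouplingProfile(fragment_starts=enc.fragment_starts, nmi=nmi, bias=bias)


def lsf_network(
    mi: np.ndarray,
    top_k: int = 500,
    node_names: list | None = None,
) -> nx.Graph:
    """Keep the k largest off-diagonal MI values as a weighted graph.

    Node attribute ``size`` is the degree (the number of retained
    interactions); asking for more links than exist keeps them all with a
    warning.
    """
    mi = np.asarray(mi, dtype=float)
    n = mi.shape[0]
    if top_k < 1:
        raise ValueError("top_k must be ≥ 1")
    iu, ju = np.triu_indices(n, k=1)
    weights = mi[iu, ju]
    n_pairs = len(weights)
    if top_k > n_pairs:
        warnings.warn(
            f"requested {top_k} links but only {n_pairs} pairs exist; keeping all",
            stacklevel=2,
        )
        top_k = n_pairs
    order = np.argsort(weights)[::-1][:top_k]
    names = node_names if node_names is not None else list(range(n))
    g = nx.Graph()
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        g.add_edge(names[i], names[j], weight=float(weights[idx]))
    for node in g.nodes:
        g.nodes[node]["size"] = g.degree[node]
    return g
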