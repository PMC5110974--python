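"""Essential-dynamics PCA, trajectory filtering, cosine content, and a
Gaussian-network-model (GNM) hinge finder.

PCA is performed on least-squares-fitted Cartesian fluctuations: frames are
superposed on a reference (translations and rotations removed), the covariance
of the 3N coordinates is diagonalized, eigenvalues are the mean-square
fluctuations along each mode (Å²) in descending order, and per-frame
projections on the modes are retained.  The cosine-content diagnostic follows
Hess's form: a projection resembling a half-period cosine (the signature of
random-walk-like, unconverged sampling) scores near 1.

The GNM hinge finder replaces an external web service: the Kirchhoff
(connectivity) matrix of the Cα contact graph is diagonalized and hinges are
reported where the slowest nonzero modes change sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import AtomSelection, Trajectory

__all__ = [
    "superpose",
    "fit_frames",
    "PCModel",
    "pca",
    "pca_matrix",
    "filter_along_mode",
    "cosine_content",
    "GNMModel",
    "gnm",
    "gnm_hinges",
]


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the weighted RMSD to
    ``reference``.  Reflections are disallowed; fewer than three points or a
    collinear point set is an error.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
    wsum = w.sum()
    mob_c = mobile - (w[:, None] * mobile).sum(0) / wsum
    ref_c = reference - (w[:, None] * reference).sum(0) / wsum
    # collinearity: centered reference must span a plane
    s = np.linalg.svd(ref_c * np.sqrt(w)[:, None], compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("points are collinear; rotation is underdetermined")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c, weights=w)
    R = rot.as_matrix()
    ref_mean = (w[:, None] * reference).sum(0) / wsum
    mob_mean = (w[:, None] * mobile).sum(0) / wsum
    t = ref_mean - mob_mean @ R.T
    rmsd = float(rssd / np.sqrt(wsum))
    return R, t, rmsd


def fit_frames(
    coords: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Superpose every frame of ``coords`` (F, N, 3) onto ``reference``."""
    out = np.empty_like(coords)
    for f in range(coords.shape[0]):
        R, t, _ = superpose(coords[f], reference, weights)
        out[f] = coords[f] @ R.T + t
    return out


@dataclass
class PCModel:
    """Covariance eigenpairs of fitted Cartesian fluctuations.

    ``eigenvectors`` has shape (n_dof, n_modes), columns orthonormal and
    oriented so the largest-magnitude entry of each mode is positive;
    ``eigenvalues`` (Å², descending) are the variances along the modes;
    ``projections`` (n_frames, n_modes) are the per-frame coordinates.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    projections: np.ndarray
    reference: np.ndarray | None = None
    selection: AtomSelection | None = None
    dt: float | None = None

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def mode_as_displacement(self, k: int) -> np.ndarray:
        """Mode k reshaped to (n_atoms, 3); only valid for coordinate PCA."""
        return self.eigenvectors[:, k].reshape(-1, 3)


def _orient_modes(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def pca_matrix(data: np.ndarray, dt: float | None = None) -> PCModel:
    """PCA of an arbitrary (n_frames, n_dof) time series via SVD.

    Eigenvalues use the population convention (divide by n_frames) so their
    sum equals the trace of the sample covariance about the mean.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2:
        raise ValueError("need a 2-D series with at least 2 frames")
    mean = data.mean(axis=0)
    centered = data - mean
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigvals = s**2 / data.shape[0]
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    vecs = _orient_modes(vt[order].T)
    projections = centered @ vecs
    return PCModel(
        mean=mean,
        eigenvalues=eigvals,
        eigenvectors=vecs,
        projections=projections,
        dt=dt,
    )


def pca(
    traj: Trajectory,
    sel: AtomSelection | None = None,
    reference: np.ndarray | None = None,
    n_modes: int | None = None,
) -> PCModel:
    """Essential-dynamics PCA of fitted Cartesian coordinates.

    Frames are first superposed on ``reference`` (default: frame 0 of the
    selection).  When ``n_modes`` exceeds the number of nontrivial modes the
    result is truncated with a warning.
    """
    sub = traj.subset(sel.as_array()) if sel is not None else traj
    if sub.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if sub.n_atoms < 3:
        raise ValueError("PCA needs a selection of at least 3 atoms")
    ref = sub.coords[0] if reference is None else np.asarray(reference, dtype=float)
    fitted = fit_frames(sub.coords, ref)
    flat = fitted.reshape(sub.n_frames, -1)
    model = pca_matrix(flat, dt=sub.dt)
    model.reference = ref
    model.selection = sel
    if n_modes is not None:
        avail = model.n_modes
        if n_modes > avail:
            warnings.warn(
                f"requested {n_modes} modes but only {avail} are available; truncating",
                stacklevel=2,
            )
            n_modes = avail
        model.eigenvalues = model.eigenvalues[:n_modes]
        model.eigenvectors = model.eigenvectors[:, :n_modes]
        model.projections = model.projections[:, :n_modes]
    return model


def filter_along_mode(traj: Trajectory, model: PCModel, mode_index: int) -> Trajectory:
    """Reconstruct frames keeping only the fluctuation along one PCA mode.

    Frames become ``mean + p_k(t) · e_k``; the returned trajectory covers the
    atoms of the model's fit selection.
    """
    if not (0 <= mode_index < model.n_modes):
        raise IndexError(f"mode {mode_index} out of range (have {model.n_modes})")
    proj = model.projections[:, mode_index]
    vec = model.eigenvectors[:, mode_index]
    flat = model.mean[None, :] + proj[:, None] * vec[None, :]
    coords = flat.reshape(len(proj), -1, 3)
    sub = traj.subset(model.selection.as_array()) if model.selection is not None else traj
    if coords.shape[1] != sub.n_atoms:
        raise ValueError("model does not describe coordinates of this trajectory")
    return Trajectory(atoms=sub.atoms, coords=coords, dt=sub.dt)


def cosine_content(model: PCModel, mode_index: int, k: int = 1) -> float:
    """Hess cosine-content diagnostic of one mode's projection.

    c = (2/T) (Σ_t p(t) cos(kπ t/T))² / Σ_t p(t)² with the half-sample time
    grid t = (i + ½)Δ; a projection equal to cos(kπ t/T) scores 1 exactly.
    """
    p = model.projections[:, mode_index]
    n = len(p)
    if n < 4:
        raise ValueError("projection too short for cosine content")
    denom = float(np.sum(p * p))
    if denom < 1e-300:
        raise ValueError("zero-variance projection; cosine content undefined")
    t = (np.arange(n) + 0.5) / n
    num = float(np.sum(p * np.cos(k * np.pi * t)))
    return float(2.0 / n * num**2 / denom)


# ---------------------------------------------------------------------------
# Gaussian network model
# ---------------------------------------------------------------------------


@dataclass
class GNMModel:
    """Kirchhoff matrix eigenpairs of a Cα contact graph.

    Rows of the Kirchhoff matrix sum to zero; the zero eigenvalue has
    multiplicity equal to the number of connected components.
    """

    kirchhoff: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    cutoff: float

    def slow_modes(self, n_modes: int, tol: float = 1e-8) -> np.ndarray:
        """The ``n_modes`` slowest nonzero modes, columns of shape (N, n)."""
        nonzero = np.nonzero(self.eigenvalues > tol)[0]
        return self.eigenvectors[:, nonzero[:n_modes]]

    def degenerate_slowest(self, tol: float = 1e-8, rel: float = 1e-6) -> bool:
        nz = self.eigenvalues[self.eigenvalues > tol]
        return len(nz) >= 2 and (nz[1] - nz[0]) <= rel * max(nz[0], 1.0)


def _connected_components(adj: np.ndarray) -> list[list[int]]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        comp = []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adj[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        comps.append(sorted(comp))
    return comps


def gnm(coords: np.ndarray, cutoff: float = 10.0) -> GNMModel:
    """Build and diagonalize the GNM Kirchhoff matrix of a Cα structure.

    Γ_ij = −1 for i≠j within ``cutoff`` Å, 0 otherwise; Γ_ii = degree.
    A disconnected contact graph is an error naming the components.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    adj = (d <= cutoff) & ~np.eye(n, dtype=bool)
    comps = _connected_components(adj)
    if len(comps) > 1:
        raise ValueError(
            f"contact graph at cutoff {cutoff} Å is disconnected; components: "
            + "; ".join(str(c[:6]) + ("..." if len(c) > 6 else "") for c in comps)
        )
    kirchhoff = -adj.astype(float)
    np.fill_diagonal(kirchhoff, adj.sum(axis=1))
    vals, vecs = np.linalg.eigh(kirchhoff)
    vecs = _orient_modes(vecs)
    return GNMModel(kirchhoff=kirchhoff, eigenvalues=vals, eigenvectors=vecs, cutoff=cutoff)


def gnm_hinges(
    structure: Trajectory | np.ndarray,
    cutoff: float = 10.0,
    n_modes: int = 2,
) -> list[list[int]]:
    """Hinge residues: sign crossovers of the slowest nonzero GNM modes.

    For each of the ``n_modes`` slowest nonzero modes, residues i and i+1 that
    bracket a sign change are reported (one list per mode).  A degenerate
    slowest eigenvalue triggers a warning since the hinge is then not unique.
    """
    if isinstance(structure, Trajectory):
        coords = structure.coords[0]
    else:
        coords = np.asarray(structure, dtype=float)
    model = gnm(coords, cutoff=cutoff)
    if model.degenerate_slowest():
        warnings.warn(
            "slowest nonzero GNM mode is degenerate; hinge assignment is not unique",
            stacklevel=2,
        )
    hinges = []
    for mode in model.slow_modes(n_modes).T:
        sign = np.sign(mode)
        cross: list[int] = []
        for i in range(len(sign) - 1):
            if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]:
                cross.extend([i, i + 1])
        hinges.append(sorted(set(cross)))
    return hinges
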