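"""Hydrogen-bond detection, existence matrices and their autocorrelation.

A hydrogen bond between a donor heavy atom D (with attached hydrogen H) and an
acceptor A is present in a frame when all three geometric criteria hold with
strict inequalities: the donor–acceptor heavy-atom distance is below
``com_distance_max`` (3.5 Å), the H···A distance is below ``oh_distance_max``
(2.6 Å), and the angular criterion is below ``angle_max`` (30°).

The angular criterion is ambiguous in common shorthand notations, so two
interpretations are offered: the default ``"hydrogen"`` vertex measures the
deviation of the D–H···A arrangement from linearity (180° − ∠DHA), the
standard geometric convention; ``"donor"`` measures the ∠H–D···A angle at the
donor heavy atom.  Results are binary per bond and frame, h_i(t) ∈ {0, 1},
and the intermittent existence autocorrelation
c(τ) = ⟨Σ_i h_i(t) h_i(t+τ)⟩_t / ⟨Σ_i h_i(t)²⟩_t averages over bonds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .trajectory import AtomSelection, Trajectory
from .vibrational import CorrelationSeries

__all__ = [
    "HBondCriterion",
    "HBondExistenceMatrix",
    "detect_hbonds",
    "existence_matrix",
    "hbond_autocorrelation",
    "fit_relaxation_time",
    "contact_map",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric H-bond criterion; defaults follow standard practice for
    far-infrared H-bond network analysis (3.5 Å / 2.6 Å / 30°, strict <)."""

    com_distance_max: float = 3.5
    oh_distance_max: float = 2.6
    angle_max: float = 30.0
    angle_vertex: str = "hydrogen"  # or "donor"

    def __post_init__(self):
        if self.com_distance_max <= 0 or self.oh_distance_max <= 0 or self.angle_max <= 0:
            raise ValueError("criterion thresholds must be positive")
        if self.angle_vertex not in ("hydrogen", "donor"):
            raise ValueError("angle_vertex must be 'hydrogen' or 'donor'")


@dataclass
class HBondExistenceMatrix:
    """Binary per-bond, per-frame indicator h_i(t).

    ``bonds`` lists (donor, hydrogen, acceptor) atom-index triples; ``matrix``
    has shape (n_bonds, n_frames) with entries in {0, 1}.
    """

    bonds: list[tuple[int, int, int]]
    matrix: np.ndarray
    dt: float

    @property
    def n_bonds(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.matrix,
            index=[f"{d}-{h}-{a}" for d, h, a in self.bonds],
        )
        df.to_csv(path, sep="\t", index_label="bond")


def _normalize_donors(donors) -> list[tuple[int, int]]:
    out = []
    for entry in donors:
        d, h = entry
        if h is None:
            warnings.warn(f"donor atom {d} has no attached hydrogen; skipped", stacklevel=3)
            continue
        out.append((int(d), int(h)))
    return out


def _angles_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("...i,...i->...", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _bond_mask(
    frame: np.ndarray,
    donors: list[tuple[int, int]],
    acceptors: np.ndarray,
    criterion: HBondCriterion,
) -> np.ndarray:
    """Boolean (n_donors, n_acceptors) presence mask for one frame."""
    d_idx = np.array([d for d, _ in donors], dtype=int)
    h_idx = np.array([h for _, h in donors], dtype=int)
    D = frame[d_idx]  # (nd, 3)
    H = frame[h_idx]
    A = frame[acceptors]  # (na, 3)
    dda = np.linalg.norm(D[:, None] - A[None, :], axis=-1)
    dha = np.linalg.norm(H[:, None] - A[None, :], axis=-1)
    if criterion.angle_vertex == "hydrogen":
        # deviation of D–H···A from linearity: 180° − angle at H
        u = D[:, None] - H[:, None]  # H→D
        v = A[None, :] - H[:, None]  # H→A
        dev = 180.0 - _angles_deg(np.broadcast_arrays(u, v)[0], np.broadcast_arrays(u, v)[1])
    else:
        u = H[:, None] - D[:, None]  # D→H
        v = A[None, :] - D[:, None]  # D→A
        dev = _angles_deg(np.broadcast_arrays(u, v)[0], np.broadcast_arrays(u, v)[1])
    mask = (
        (dda < criterion.com_distance_max)
        & (dha < criterion.oh_distance_max)
        & (dev < criterion.angle_max)
    )
    # a donor cannot bond to itself
    mask &= d_idx[:, None] != np.asarray(acceptors)[None, :]
    return mask


def detect_hbonds(
    frame: np.ndarray,
    donors,
    acceptors,
    criterion: HBondCriterion | None = None,
) -> list[tuple[int, int, int]]:
    """Hydrogen bonds present in a single frame.

    ``donors`` is a sequence of (donor_heavy_atom, hydrogen) index pairs and
    ``acceptors`` a sequence of heavy-atom indices.  Returns (D, H, A) triples
    satisfying all three strict criteria.
    """
    criterion = criterion or HBondCriterion()
    donors = _normalize_donors(donors)
    acceptors = np.asarray(list(acceptors), dtype=int)
    frame = np.asarray(frame, dtype=float)
    mask = _bond_mask(frame, donors, acceptors, criterion)
    out = []
    for (di, (d, h)) in enumerate(donors):
        for ai in np.nonzero(mask[di])[0]:
            out.append((d, h, int(acceptors[ai])))
    return out


def existence_matrix(
    traj: Trajectory,
    donors,
    acceptors,
    criterion: HBondCriterion | None = None,
) -> HBondExistenceMatrix:
    """Per-frame binary existence matrix over the union of observed bonds.

    The bond universe is every (D, H, A) triple present in at least one frame;
    frames where a universe bond is absent contribute 0.
    """
    criterion = criterion or HBondCriterion()
    donors = _normalize_donors(donors)
    acceptors = np.asarray(list(acceptors), dtype=int)
    masks = np.stack(
        [_bond_mask(traj.coords[f], donors, acceptors, criterion) for f in range(traj.n_frames)]
    )  # (T, nd, na)
    ever = masks.any(axis=0)
    bonds = []
    rows = []
    for di, (d, h) in enumerate(donors):
        for ai in np.nonzero(ever[di])[0]:
            bonds.append((d, h, int(acceptors[ai])))
            rows.append(masks[:, di, ai])
    if not bonds:
        warnings.warn("no hydrogen bond found in any frame; matrix is empty", stacklevel=2)
        return HBondExistenceMatrix(bonds=[], matrix=np.zeros((0, traj.n_frames), dtype=int), dt=traj.dt)
    return HBondExistenceMatrix(
        bonds=bonds, matrix=np.stack(rows).astype(int), dt=traj.dt
    )


def hbond_autocorrelation(
    mat: HBondExistenceMatrix,
    max_lag_fs: float | None = None,
    continuous: bool = False,
) -> CorrelationSeries:
    """H-bond existence autocorrelation averaged over bonds.

    The default intermittent definition credits a bond at lag τ whenever it is
    formed at both endpoints, regardless of breaks in between; the
    ``continuous`` variant requires the bond to persist over the whole lag.
    c(0) = 1 exactly for any non-empty matrix.
    """
    h = np.asarray(mat.matrix, dtype=float)
    if h.size == 0 or h.sum() == 0:
        raise ValueError("empty existence matrix")
    T = h.shape[1]
    n_lags = T if max_lag_fs is None else int(round(max_lag_fs / mat.dt)) + 1
    if n_lags > T:
        raise ValueError("max_lag must be shorter than the total duration")
    if continuous:
        # product h(t)h(t+1)...h(t+τ) via running minimum of cumulative gaps
        values = np.empty(n_lags)
        denom = h.sum() / T
        run = h.copy()
        values[0] = 1.0
        for lag in range(1, n_lags):
            run = run[:, :-1] * h[:, lag:]
            values[lag] = (run.sum() / (T - lag)) / denom
        counts = T - np.arange(n_lags)
        return CorrelationSeries(lags=np.arange(n_lags) * mat.dt, values=values, n_samples=counts)
    from .vibrational import _fft_autocorr_sums

    sums = _fft_autocorr_sums(h.T)[:n_lags]
    counts = T - np.arange(n_lags)
    numerator = sums / counts
    denom = h.sum() / T  # Σ h² = Σ h for binary h
    return CorrelationSeries(
        lags=np.arange(n_lags) * mat.dt,
        values=numerator / denom,
        n_samples=counts,
    )


def fit_relaxation_time(corr: CorrelationSeries) -> tuple[float, float, float]:
    """Fit A·exp(−τ/τ_c) + B to a correlation series; returns (τ_c, A, B)."""

    def model(tau, a, tau_c, b):
        return a * np.exp(-tau / tau_c) + b

    lags = np.asarray(corr.lags, dtype=float)
    vals = np.asarray(corr.values, dtype=float)
    span = max(lags[-1], 1.0)
    p0 = (max(vals[0] - vals[-1], 1e-3), span / 10.0, vals[-1])
    popt, _ = curve_fit(model, lags, vals, p0=p0, maxfev=10000)
    return float(popt[1]), float(popt[0]), float(popt[2])


def contact_map(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float,
) -> pd.DataFrame:
    """Fraction of frames each cross-pair lies within ``cutoff`` Å.

    ``cutoff`` is mandatory: what counts as a weak contact depends on the
    interaction class being screened.  Self-pairs are excluded when the
    selections overlap.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ia = sel_a.as_array()
    ib = sel_b.as_array()
    da = traj.coords[:, ia][:, :, None, :]
    db = traj.coords[:, ib][:, None, :, :]
    within = np.linalg.norm(da - db, axis=-1) < cutoff
    freq = within.mean(axis=0)
    rows = []
    for x, i in enumerate(ia):
        for y, j in enumerate(ib):
            if i == j:
                continue
            rows.append((int(i), int(j), float(freq[x, y])))
    return pd.DataFrame(rows, columns=["atom_a", "atom_b", "frequency"])
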