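"""Trajectory containers, file I/O, atom selections and geometric time series.

The canonical velocity-carrying on-disk format is a small extended-XYZ dialect:
each frame is ``n_atoms`` / comment / atom lines, the comment line carries
``dt_fs=<float> frame=<int>``, and each atom line is
``element x y z [vx vy vz]`` (whitespace separated, Å and Å/fs).
Multi-model PDB (one MODEL per frame) is supported through biotite; PDB files
carry no time step, so ``dt`` must then be passed explicitly.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ATOMIC_MASSES, DEFAULT_MASS

__all__ = [
    "Trajectory",
    "AtomSelection",
    "AngleSeries",
    "read_trajectory",
    "write_xyz",
    "write_pdb",
    "select",
    "angle_series",
    "SelectionError",
]


def _mass_for(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), DEFAULT_MASS)


@dataclass
class Trajectory:
    """Ordered frames of positions (and optionally velocities) for one atom set.

    Attributes
    ----------
    atoms : pandas.DataFrame
        Per-atom table with columns ``name``, ``resid`` (0-based internal),
        ``resname``, ``element``, ``mass``.
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Positions in Å.
    velocities : ndarray or None, shape (n_frames, n_atoms, 3)
        Velocities in Å/fs, if the source carried them.
    dt : float
        Frame spacing in fs.
    """

    atoms: pd.DataFrame
    coords: np.ndarray
    dt: float
    velocities: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table and coordinate array disagree on atom count")
        if not np.isfinite(self.coords).all():
            raise ValueError("positions must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.coords.shape:
                raise ValueError("velocities must match coords in shape")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    def subset(self, indices: Sequence[int]) -> "Trajectory":
        """New trajectory restricted to the given atom indices (order kept)."""
        idx = np.asarray(indices, dtype=int)
        return Trajectory(
            atoms=self.atoms.iloc[idx].reset_index(drop=True),
            coords=self.coords[:, idx],
            dt=self.dt,
            velocities=None if self.velocities is None else self.velocities[:, idx],
        )

    @staticmethod
    def from_arrays(
        coords: np.ndarray,
        dt: float,
        velocities: np.ndarray | None = None,
        elements: Sequence[str] | None = None,
        resids: Sequence[int] | None = None,
        resnames: Sequence[str] | None = None,
        names: Sequence[str] | None = None,
        masses: Sequence[float] | None = None,
    ) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)
        n_atoms = coords.shape[1]
        elements = list(elements) if elements is not None else ["C"] * n_atoms
        atoms = pd.DataFrame(
            {
                "name": list(names) if names is not None else elements,
                "resid": list(resids) if resids is not None else list(range(n_atoms)),
                "resname": list(resnames) if resnames is not None else ["UNK"] * n_atoms,
                "element": elements,
                "mass": (
                    list(masses)
                    if masses is not None
                    else [_mass_for(e) for e in elements]
                ),
            }
        )
        return Trajectory(atoms=atoms, coords=coords, dt=dt, velocities=velocities)


# ---------------------------------------------------------------------------
# extended XYZ dialect
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"dt_fs=([0-9.eE+-]+)")


def write_xyz(traj: Trajectory, path: str | Path, precision: int = 8) -> None:
    """Write the extended-XYZ dialect; velocities are included when present."""
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"dt_fs={traj.dt:g} frame={f}\n")
            for a in range(traj.n_atoms):
                parts = [traj.atoms["element"].iloc[a]]
                parts += [fmt % v for v in traj.coords[f, a]]
                if traj.velocities is not None:
                    parts += [fmt % v for v in traj.velocities[f, a]]
                fh.write(" ".join(parts) + "\n")


def _read_xyz(path: str | Path, dt: float | None) -> Trajectory:
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos_frames: list[np.ndarray] = []
    vel_frames: list[np.ndarray] = []
    elements: list[str] | None = None
    file_dt: float | None = None
    i = 0
    frame_no = 0
    has_velocities: bool | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {frame_no}: expected atom count, got {lines[i]!r}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        m = _COMMENT_RE.search(comment)
        if m:
            file_dt = float(m.group(1))
        body = lines[i + 2 : i + 2 + n]
        if len(body) < n:
            raise ValueError(f"frame {frame_no}: declared {n} atoms but file ended early")
        frame_elements: list[str] = []
        pos = np.empty((n, 3))
        vel = np.empty((n, 3))
        frame_has_vel = None
        for j, line in enumerate(body):
            tok = line.split()
            if len(tok) not in (4, 7):
                raise ValueError(
                    f"frame {frame_no}, atom {j + 1}: expected 4 or 7 columns, got {len(tok)}"
                )
            frame_elements.append(tok[0])
            pos[j] = [float(t) for t in tok[1:4]]
            this_has_vel = len(tok) == 7
            if frame_has_vel is None:
                frame_has_vel = this_has_vel
            elif frame_has_vel != this_has_vel:
                raise ValueError(f"frame {frame_no}: mixed velocity columns")
            if this_has_vel:
                vel[j] = [float(t) for t in tok[4:7]]
        if elements is None:
            elements = frame_elements
            has_velocities = frame_has_vel
        else:
            if len(frame_elements) != len(elements):
                raise ValueError(
                    f"frame {frame_no}: atom count {len(frame_elements)} does not match "
                    f"frame 1 ({len(elements)})"
                )
            if frame_has_vel != has_velocities:
                raise ValueError(f"frame {frame_no}: velocity columns inconsistent with frame 1")
        pos_frames.append(pos)
        if frame_has_vel:
            vel_frames.append(vel)
        i += 2 + n
    if not pos_frames:
        raise ValueError("no frames found")
    use_dt = dt if dt is not None else file_dt
    if use_dt is None:
        raise ValueError("file carries no dt_fs header; pass dt explicitly")
    return Trajectory.from_arrays(
        coords=np.stack(pos_frames),
        dt=use_dt,
        velocities=np.stack(vel_frames) if vel_frames else None,
        elements=elements,
    )


# ---------------------------------------------------------------------------
# multi-model PDB via biotite
# ---------------------------------------------------------------------------


def write_pdb(traj: Trajectory, path: str | Path, b_factors: np.ndarray | None = None) -> None:
    """Write a multi-model PDB (one MODEL per frame) via biotite.

    ``b_factors`` (per atom) lets callers map scalar profiles such as punctual
    stress into the B-factor column.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    arr = struc.AtomArrayStack(traj.n_frames, n)
    arr.coord = traj.coords.copy()
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.asarray(traj.atoms["resid"], dtype=int) + 1  # 1-based on disk
    arr.res_name = np.asarray(traj.atoms["resname"], dtype="U5")
    arr.atom_name = np.asarray(traj.atoms["name"], dtype="U6")
    arr.element = np.asarray(traj.atoms["element"], dtype="U2")
    arr.set_annotation("hetero", np.zeros(n, dtype=bool))
    if b_factors is not None:
        arr.set_annotation("b_factor", np.asarray(b_factors, dtype=float))
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _read_pdb(path: str | Path, dt: float | None) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    if dt is None:
        raise ValueError("PDB carries no time step; pass dt explicitly")
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:  # single model
        coords = coords[None]
    elements = [e if e else "C" for e in stack.element]
    return Trajectory.from_arrays(
        coords=coords,
        dt=dt,
        elements=elements,
        resids=(np.asarray(stack.res_id, dtype=int) - 1).tolist(),
        resnames=list(stack.res_name),
        names=list(stack.atom_name),
    )


def read_trajectory(path: str | Path, fmt: str | None = None, dt: float | None = None) -> Trajectory:
    """Read a trajectory from extended XYZ or multi-model PDB.

    ``fmt`` is inferred from the suffix when omitted ("xyz" or "pdb").
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "xyz":
        return _read_xyz(path, dt)
    if fmt == "pdb":
        return _read_pdb(path, dt)
    raise ValueError(f"unknown trajectory format {fmt!r}")


# ---------------------------------------------------------------------------
# atom selection expressions
# ---------------------------------------------------------------------------


class SelectionError(ValueError):
    """Raised for selection-expression syntax errors; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at token position {position})")
        self.position = position


@dataclass(frozen=True)
class AtomSelection:
    """Ordered, unique atom indices plus the expression they came from."""

    indices: tuple[int, ...]
    expression: str

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not", "all", "resid", "resname", "name", "element"}
_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")


class _Parser:
    """Recursive-descent parser for the selection grammar.

    expr  := term (OR term)*
    term  := factor (AND factor)*
    factor:= NOT factor | '(' expr ')' | primary
    primary := 'all' | 'resid' ranges+ | ('name'|'resname'|'element') values+
    """

    def __init__(self, tokens: list[str], atoms: pd.DataFrame):
        self.tokens = tokens
        self.pos = 0
        self.atoms = atoms

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of expression", self.pos)
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}", self.pos)
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.peek() != ")":
                raise SelectionError("expected ')'", self.pos)
            self.take()
            return mask
        return self.primary()

    def _values(self) -> list[str]:
        vals = []
        while self.peek() is not None and self.peek() not in _KEYWORDS and self.peek() not in "()":
            vals.append(self.take())
        if not vals:
            raise SelectionError("expected at least one value", self.pos)
        return vals

    def primary(self) -> np.ndarray:
        tok = self.take()
        n = len(self.atoms)
        if tok == "all":
            return np.ones(n, dtype=bool)
        if tok == "resid":
            mask = np.zeros(n, dtype=bool)
            resid = self.atoms["resid"].to_numpy()
            for val in self._values():
                m = _RANGE_RE.match(val)
                if m:
                    lo, hi = int(m.group(1)), int(m.group(2))
                    mask |= (resid >= lo) & (resid <= hi)
                else:
                    try:
                        mask |= resid == int(val)
                    except ValueError as exc:
                        raise SelectionError(f"bad resid value {val!r}", self.pos - 1) from exc
            return mask
        if tok in ("name", "resname", "element"):
            col = self.atoms[tok].astype(str).str.upper().to_numpy()
            vals = {v.upper() for v in self._values()}
            return np.isin(col, list(vals))
        raise SelectionError(f"unknown keyword {tok!r}", self.pos - 1)


def select(traj: Trajectory, expression: str) -> AtomSelection:
    """Evaluate a selection expression against the trajectory's atom table.

    Empty results are legal (a warning is emitted); syntax errors raise
    :class:`SelectionError` carrying the failing token position.
    """
    tokens = _TOKEN_RE.findall(expression)
    if not tokens:
        raise SelectionError("empty expression", 0)
    mask = _Parser(tokens, traj.atoms).parse()
    indices = tuple(int(i) for i in np.nonzero(mask)[0])
    if not indices:
        warnings.warn(f"selection {expression!r} matched no atoms", stacklevel=2)
    return AtomSelection(indices=indices, expression=expression)


# ---------------------------------------------------------------------------
# geometric time series
# ---------------------------------------------------------------------------


@dataclass
class AngleSeries:
    """Per-frame angle (three points, degrees in [0, 180]) or signed dihedral
    (four points, degrees in (−180, 180], IUPAC convention: cis = 0°).

    ``undefined`` flags frames where the construction is degenerate
    (collinear points within tolerance).
    """

    values: np.ndarray
    definition: tuple
    dt: float
    undefined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.undefined is None:
            self.undefined = np.isnan(self.values)


def _point_series(traj: Trajectory, spec) -> np.ndarray:
    """A point per frame: an atom index, or a group of indices (centroid)."""
    if isinstance(spec, AtomSelection):
        idx = spec.as_array()
    else:
        idx = np.atleast_1d(np.asarray(spec, dtype=int))
    if idx.min() < 0 or idx.max() >= traj.n_atoms:
        raise IndexError(f"atom index out of range in point definition {spec!r}")
    return traj.coords[:, idx].mean(axis=1)


_COLLINEAR_TOL = 1e-8


def angle_series(traj: Trajectory, definition: Sequence) -> AngleSeries:
    """Angle (3 points) or signed dihedral (4 points) per frame.

    Each definition entry is an atom index or an index group whose centroid is
    used — e.g. three methyl-group centroids give a three-point group angle.
    Degenerate frames are flagged NaN rather than raising.
    """
    pts = [_point_series(traj, p) for p in definition]
    if len(pts) == 3:
        a, b, c = pts
        u = a - b
        v = c - b
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        bad = (nu < _COLLINEAR_TOL) | (nv < _COLLINEAR_TOL)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", u, v) / (nu * nv)
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        bad |= cross < _COLLINEAR_TOL * np.maximum(nu * nv, 1.0)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        ang[bad] = np.nan
        return AngleSeries(values=ang, definition=tuple(map(_def_key, definition)), dt=traj.dt)
    if len(pts) == 4:
        p0, p1, p2, p3 = pts
        b1 = p1 - p0
        b2 = p2 - p1
        b3 = p3 - p2
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=1, keepdims=True))
        x = np.einsum("ij,ij->i", n1, n2)
        y = np.einsum("ij,ij->i", m1, n2)
        bad = (np.linalg.norm(n1, axis=1) < _COLLINEAR_TOL) | (
            np.linalg.norm(n2, axis=1) < _COLLINEAR_TOL
        )
        # IUPAC: cis (eclipsed) = 0°, trans = 180°
        dihed = np.degrees(np.arctan2(y, x))
        dihed = np.where(dihed <= -180.0, dihed + 360.0, dihed)
        dihed[bad] = np.nan
        return AngleSeries(values=dihed, definition=tuple(map(_def_key, definition)), dt=traj.dt)
    raise ValueError("definition must name three or four points")


def _def_key(spec):
    if isinstance(spec, AtomSelection):
        return spec.expression
    arr = np.atleast_1d(np.asarray(spec, dtype=int))
    return int(arr[0]) if arr.size == 1 else tuple(int(i) for i in arr)
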