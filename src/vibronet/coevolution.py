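"""Coevolution analysis of protein multiple sequence alignments.

Pipeline: sequences are weighted by identity clustering (each cluster of
sequences at least 62% identical shares unit weight), weighted amino-acid
pair frequencies with a low-count (pseudocount) correction are compared with
the product of the single-column frequencies, and the mutual information of a
column pair is the weighted sum of log ratios of observed over expected pair
frequencies.  Raw MI is standardized into z-scores against a null built from
many column-wise randomized alignments (shuffling within a column preserves
its composition but destroys covariation); a z ≥ 6.5 threshold flags coupled
positions.  Per-column conservation is the Kullback–Leibler divergence of the
column's composition from a background profile.

Gaps are a 21st symbol for bookkeeping but are excluded pairwise from counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "WeightedMSA",
    "sequence_weights",
    "pair_frequencies",
    "mi_scores",
    "MIZResult",
    "z_scores",
    "conservation",
    "connectivity_ranking",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_ALPHABET = AMINO_ACIDS + GAP
_CODE = {a: i for i, a in enumerate(_ALPHABET)}
N_AA = 20
GAP_CODE = 20


def encode_sequences(seqs: list[str]) -> np.ndarray:
    """Aligned sequences → integer codes (n_seq, n_col); unknowns → gap."""
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences are not aligned (unequal lengths)")
    arr = np.full((len(seqs), lengths.pop()), GAP_CODE, dtype=np.int8)
    for i, s in enumerate(seqs):
        for j, ch in enumerate(s.upper()):
            arr[i, j] = _CODE.get(ch, GAP_CODE)
    return arr


@dataclass
class WeightedMSA:
    """An aligned set of sequences with per-sequence clustering weights."""

    codes: np.ndarray  # (n_seq, n_col) int8, 0..19 amino acids, 20 gap
    ids: list[str]
    weights: np.ndarray | None = None
    reference_id: str | None = None

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    @property
    def n_columns(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_fasta(cls, path: str | Path, reference_id: str | None = None) -> "WeightedMSA":
        import biotite.sequence.io.fasta as fasta

        ff = fasta.FastaFile.read(str(path))
        ids = list(ff.keys())
        seqs = [ff[i] for i in ids]
        return cls(codes=encode_sequences(seqs), ids=ids, reference_id=reference_id)

    def to_fasta(self, path: str | Path) -> None:
        import biotite.sequence.io.fasta as fasta

        ff = fasta.FastaFile()
        for i, sid in enumerate(self.ids):
            ff[sid] = "".join(_ALPHABET[c] for c in self.codes[i])
        ff.write(str(path))

    def reference_column_map(self) -> dict[int, int]:
        """Alignment column → residue number (1-based) in the reference
        sequence; columns gapped in the reference are absent."""
        if self.reference_id is None:
            raise ValueError("no reference sequence set")
        row = self.codes[self.ids.index(self.reference_id)]
        mapping = {}
        res = 0
        for col, code in enumerate(row):
            if code != GAP_CODE:
                res += 1
                mapping[col] = res
        return mapping


def sequence_weights(msa: WeightedMSA, identity_threshold: float = 0.62) -> np.ndarray:
    """Identity-clustering weights: 1 / cluster size.

    Sequences are clustered single-linkage at pairwise identity ≥ threshold
    (identity over columns where at least one sequence is ungapped).  All-gap
    sequences are excluded (weight 0) with a warning.
    """
    if not (0.0 < identity_threshold < 1.0):
        raise ValueError("identity threshold must be in (0, 1)")
    codes = msa.codes
    n = codes.shape[0]
    gapped = codes == GAP_CODE
    all_gap = gapped.all(axis=1)
    if all_gap.any():
        warnings.warn(
            f"{all_gap.sum()} all-gap sequence(s) excluded from weighting", stacklevel=2
        )
    # pairwise identity
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        if all_gap[i]:
            continue
        eq = codes[i][None, :] == codes[i + 1 :]
        comp = ~(gapped[i][None, :] & gapped[i + 1 :])
        n_comp = comp.sum(axis=1)
        match = (eq & comp).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ident = np.where(n_comp > 0, match / np.maximum(n_comp, 1), 0.0)
        for off in np.nonzero(ident >= identity_threshold)[0]:
            j = i + 1 + int(off)
            if all_gap[j]:
                continue
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(n)])
    weights = np.zeros(n)
    for r in np.unique(roots[~all_gap]):
        members = np.nonzero((roots == r) & ~all_gap)[0]
        weights[members] = 1.0 / len(members)
    return weights


def _one_hot_weighted(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """(n_col, n_seq, 20) weighted one-hot with gaps zeroed."""
    n_seq, n_col = codes.shape
    oh = np.zeros((n_col, n_seq, N_AA))
    cc = codes.T  # (n_col, n_seq)
    valid = cc != GAP_CODE
    cols, seqs = np.nonzero(valid)
    oh[cols, seqs, cc[cols, seqs]] = weights[seqs]
    return oh


def _pair_count_tensor(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted joint counts for every column pair: (n_col, 20, n_col, 20).

    Gapped positions carry zero one-hot weight, so any sequence gapped in
    either column of a pair is excluded from that pair's counts.
    """
    oh = _one_hot_weighted(codes, weights)  # (C, S, 20)
    C, S, A = oh.shape
    flat = oh.transpose(0, 2, 1).reshape(C * A, S)
    # weights would appear squared in the Gram product; take sqrt so each
    # sequence contributes its weight exactly once per pair
    flat_sqrt = np.sqrt(flat)
    G = flat_sqrt @ flat_sqrt.T
    return G.reshape(C, A, C, A).transpose(0, 2, 1, 3)  # (C, C, 20, 20)


def pair_frequencies(
    msa: WeightedMSA,
    weights: np.ndarray | None = None,
    pseudocount: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected pair-frequency tables for all column pairs.

    Returns ``(observed, expected)`` of shape (n_col, n_col, 20, 20):
    observed = weighted pair counts plus a uniform pseudocount of
    ``pseudocount`` × total weight, renormalized; expected is the outer
    product of the observed table's own marginals.  Columns containing only
    gaps are flagged with a warning and yield zero tables.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be ≥ 0")
    w = weights if weights is not None else np.ones(msa.n_sequences)
    joint = _pair_count_tensor(msa.codes, w)
    all_gap_cols = (msa.codes == GAP_CODE).all(axis=0)
    if all_gap_cols.any():
        warnings.warn(
            f"column(s) {np.nonzero(all_gap_cols)[0].tolist()} contain only gaps; excluded",
            stacklevel=2,
        )
    total_w = float(w.sum())
    joint = joint + pseudocount * total_w / (N_AA * N_AA)
    if all_gap_cols.any():
        joint[all_gap_cols] = 0.0
        joint[:, all_gap_cols] = 0.0
    sums = joint.sum(axis=(2, 3), keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(sums > 0, joint / np.where(sums > 0, sums, 1.0), 0.0)
    pa = observed.sum(axis=3)  # (C, C, 20): marginal of column i within pair
    pb = observed.sum(axis=2)  # (C, C, 20): marginal of column j within pair
    expected = pa[..., :, None] * pb[..., None, :]
    return observed, expected


def mi_scores(observed: np.ndarray, expected: np.ndarray) -> np.ndarray:
    """Pairwise MI matrix: Σ_ab f(a,b) log[f(a,b)/(f(a)f(b))], 0·log0 = 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((observed > 0) & (expected > 0), observed / expected, 1.0)
        mi = (observed * np.log(ratio)).sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    return mi


def msa_mi(
    msa: WeightedMSA, weights: np.ndarray | None = None, pseudocount: float = 0.05
) -> np.ndarray:
    """Convenience: weighted, pseudocounted MI matrix of an alignment."""
    obs, exp = pair_frequencies(msa, weights, pseudocount)
    return mi_scores(obs, exp)


@dataclass
class MIZResult:
    """Raw MI, z-scores against randomized-alignment nulls, and the ranked
    pairs at or above the threshold (default 6.5)."""

    mi: np.ndarray
    z: np.ndarray
    null_mean: float | np.ndarray
    null_sd: float | np.ndarray
    threshold: float
    significant: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.significant is None:
            iu, ju = np.triu_indices(self.mi.shape[0], k=1)
            mask = self.z[iu, ju] >= self.threshold
            df = pd.DataFrame(
                {
                    "col_i": iu[mask],
                    "col_j": ju[mask],
                    "mi": self.mi[iu, ju][mask],
                    "z": self.z[iu, ju][mask],
                }
            ).sort_values("z", ascending=False, ignore_index=True)
            self.significant = df


def z_scores(
    msa: WeightedMSA,
    weights: np.ndarray | None = None,
    n_randomizations: int = 100,
    seed: int | np.random.Generator = 0,
    pseudocount: float = 0.05,
    threshold: float = 6.5,
    pooled_null: bool = True,
) -> MIZResult:
    """MI z-scores against column-shuffled randomized alignments.

    Each randomization independently permutes the residues within every
    column, preserving column composition while destroying covariation.  The
    z-score of a pair is the number of null standard deviations its observed
    MI lies above the null mean; the default pools the null over all pairs
    (stable for short alignments), ``pooled_null=False`` uses per-pair
    moments.  Pairs with z ≥ ``threshold`` (default 6.5) are reported ranked.
    """
    if n_randomizations < 20:
        raise ValueError("use at least 20 randomizations for a usable null")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = weights if weights is not None else np.ones(msa.n_sequences)
    mi = msa_mi(msa, w, pseudocount)
    C = msa.n_columns
    iu, ju = np.triu_indices(C, k=1)
    null_vals = np.empty((n_randomizations, len(iu)))
    codes = msa.codes
    for r in range(n_randomizations):
        shuffled = np.empty_like(codes)
        for c in range(C):
            perm = rng.permutation(msa.n_sequences)
            shuffled[:, c] = codes[perm, c]
        null_mi = msa_mi(
            WeightedMSA(codes=shuffled, ids=msa.ids), w, pseudocount
        )
        null_vals[r] = null_mi[iu, ju]
    if pooled_null:
        mean = float(null_vals.mean())
        sd = float(null_vals.std(ddof=1))
        if sd == 0.0:
            raise ValueError("null distribution has zero spread")
        z_flat = (mi[iu, ju] - mean) / sd
    else:
        mean = null_vals.mean(axis=0)
        sd = null_vals.std(axis=0, ddof=1)
        z_flat = np.full(len(iu), np.nan)
        ok = sd > 0
        z_flat[ok] = (mi[iu, ju][ok] - mean[ok]) / sd[ok]
        if (~ok).any():
            warnings.warn(
                f"{(~ok).sum()} pair(s) have zero null SD; z undefined there", stacklevel=2
            )
    z = np.zeros((C, C))
    z[iu, ju] = z_flat
    z[ju, iu] = z_flat
    return MIZResult(mi=mi, z=z, null_mean=mean, null_sd=sd, threshold=threshold)


def conservation(
    msa: WeightedMSA,
    weights: np.ndarray | None = None,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Per-column Kullback–Leibler divergence from a background profile.

    Gaps are excluded and the column composition renormalized; a uniform
    background is the default.  All-gap columns are NaN with a warning.
    """
    w = weights if weights is not None else np.ones(msa.n_sequences)
    bg = (
        np.full(N_AA, 1.0 / N_AA)
        if background is None
        else np.asarray(background, dtype=float)
    )
    if (bg <= 0).any():
        raise ValueError("background must be strictly positive")
    bg = bg / bg.sum()
    C = msa.n_columns
    out = np.empty(C)
    for c in range(C):
        col = msa.codes[:, c]
        valid = col != GAP_CODE
        if not valid.any():
            out[c] = np.nan
            continue
        freq = np.bincount(col[valid], weights=w[valid], minlength=N_AA)[:N_AA]
        total = freq.sum()
        if total == 0:
            out[c] = np.nan
            continue
        p = freq / total
        nz = p > 0
        out[c] = float((p[nz] * np.log(p[nz] / bg[nz])).sum())
    if np.isnan(out).any():
        warnings.warn("all-gap column(s) have undefined conservation", stacklevel=2)
    return out


def connectivity_ranking(result: MIZResult, top_k: int = 500) -> pd.DataFrame:
    """Rank columns by degree in the top-k z-score network.

    The ``top_k`` strongest pairs by z (ties broken toward lower column
    indices) define an unweighted graph; nodes are ranked by degree.
    """
    if top_k < 1:
        raise ValueError("top_k must be ≥ 1")
    C = result.z.shape[0]
    iu, ju = np.triu_indices(C, k=1)
    zvals = result.z[iu, ju]
    order = sorted(range(len(zvals)), key=lambda k: (-zvals[k], int(iu[k]), int(ju[k])))
    order = order[:top_k]
    degree: dict[int, int] = {}
    for k in order:
        degree[int(iu[k])] = degree.get(int(iu[k]), 0) + 1
        degree[int(ju[k])] = degree.get(int(ju[k]), 0) + 1
    df = pd.DataFrame(
        {"column": list(degree.keys()), "degree": list(degree.values())}
    ).sort_values(["degree", "column"], ascending=[False, True], ignore_index=True)
    return df
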