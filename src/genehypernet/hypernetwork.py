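"""Manhattan-distance incidence matrices and M·Mᵀ hypernetworks.

Given a gene set of interest (rows) and the whole transcriptome
(columns), the distance matrix holds Manhattan (L1) distances between
expression profiles over one condition's samples. Binarising it at a
centile threshold keeps only the closest relationships as a 0/1
incidence matrix M; the hypernetwork H = M·Mᵀ then counts, for every
pair of set genes, how many transcripts both are close to. Connectivity
is the mean entry of H; per-gene Shannon entropy of the row-normalised
off-diagonal profile measures how concentrated (low entropy) or diffuse
(high entropy) a gene's shared relationships are.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .matrix import ExpressionMatrix


@dataclass
class DistanceMatrix:
    """Gene-set × transcriptome Manhattan distances.

    ``values[i, j]`` is the L1 distance between row gene i and column
    gene j over the selected samples; a row gene's own column is masked
    to NaN so a trivial self-distance of zero cannot enter the
    binarisation threshold or the incidence matrix.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    sample_ids: list[str]
    transform: str

    @property
    def n_set(self) -> int:
        return self.values.shape[0]

    @property
    def n_total(self) -> int:
        return self.values.shape[1]


@dataclass
class IncidenceMatrix:
    """Binary matrix M marking the closest gene relationships.

    ``values[i, j] = 1`` iff the distance from set gene i to transcript
    j was at or below the centile threshold; masked self-pairs stay 0.
    """

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    centile: float
    threshold: float


@dataclass
class Hypernetwork:
    """H = M·Mᵀ of shared-relationship counts, with its summaries."""

    H: np.ndarray
    gene_ids: list[str]
    connectivity: float
    connectivity_no_diagonal: float
    entropy: np.ndarray

    @property
    def n_set(self) -> int:
        return self.H.shape[0]

    @property
    def median_entropy(self) -> float:
        return float(np.median(self.entropy))


def manhattan_distance_matrix(
    matrix: ExpressionMatrix,
    gene_set,
    condition_samples,
    transform: str = "log2p1",
) -> DistanceMatrix:
    """Manhattan distances from each set gene to every transcript.

    ``condition_samples`` may be a condition label or an explicit list
    of sample ids. ``transform="log2p1"`` computes distances on
    log2(x + 1) so a handful of highly expressed genes cannot dominate
    the metric; ``"none"`` uses the values as-is.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    if isinstance(condition_samples, str):
        samples = matrix.samples_of(condition_samples)
    else:
        samples = list(condition_samples)
        unknown = [s for s in samples if s not in matrix.values.columns]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
    if not samples:
        raise ValueError("no samples selected")
    missing = [g for g in gene_set if g not in matrix.values.index]
    if missing:
        raise KeyError(f"gene set members absent from matrix: {missing[:5]}")
    if transform not in ("log2p1", "none"):
        raise ValueError(f"unknown transform {transform!r}")

    X = matrix.values[samples].to_numpy(dtype=float)
    if transform == "log2p1":
        X = np.log2(X + 1.0)
    col_ids = list(matrix.values.index)
    pos = {g: i for i, g in enumerate(col_ids)}
    rows = np.array([pos[g] for g in gene_set])
    D = cdist(X[rows], X, metric="cityblock")
    D[np.arange(len(rows)), rows] = np.nan  # mask self-pairs
    return DistanceMatrix(D, gene_set, col_ids, samples, transform)


def binarise(
    dist: DistanceMatrix, centile: float = 30.0, per_row: bool = False
) -> IncidenceMatrix:
    """Threshold distances at a centile, keeping the closest relationships.

    The threshold is the linear-interpolation quantile (centile/100)
    over all finite entries; entries at or below it (ties included)
    become 1. ``per_row=True`` thresholds each row at its own centile
    instead of one global cut, for sensitivity analyses.
    """
    if not 0 < centile < 100:
        raise ValueError("centile must lie strictly between 0 and 100")
    vals = dist.values
    if vals.size == 0 or not np.isfinite(vals).any():
        raise ValueError("empty distance matrix")
    q = centile / 100.0
    if per_row:
        t_rows = np.nanquantile(vals, q, axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            M = vals <= t_rows
        threshold = float(np.median(t_rows))
    else:
        flat = vals.ravel()
        finite = flat[np.isfinite(flat)]  # drop masked self-pairs
        threshold = float(np.quantile(finite, q))
        with np.errstate(invalid="ignore"):
            M = vals <= threshold  # NaN compares False: self-pairs stay 0
    return IncidenceMatrix(
        M.astype(np.uint8), list(dist.row_ids), list(dist.col_ids), centile, threshold
    )


def build_hypernetwork(M: IncidenceMatrix, include_diagonal: bool = True) -> Hypernetwork:
    """Form H = M·Mᵀ and populate connectivity and per-gene entropy.

    H[i, j] counts the transcripts that set genes i and j are both
    close to; the diagonal holds each gene's own neighbourhood size.
    ``include_diagonal`` selects which connectivity variant fills the
    ``connectivity`` field (both are always computed).
    """
    vals = np.asarray(M.values)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("incidence matrix must be binary")
    # float BLAS product, exact for these integer-valued matrices
    Mf = vals.astype(np.float64)
    H = np.rint(Mf @ Mf.T).astype(np.int64)
    conn_diag = connectivity(H, include_diagonal=True)
    conn_nodiag = connectivity(H, include_diagonal=False)
    ent = entropy_per_gene(H) if H.shape[0] >= 2 else np.zeros(H.shape[0])
    return Hypernetwork(
        H,
        list(M.row_ids),
        conn_diag if include_diagonal else conn_nodiag,
        conn_nodiag,
        ent,
    )


def connectivity(H: np.ndarray, include_diagonal: bool = True) -> float:
    """Mean entry of the hypernetwork matrix."""
    H = np.asarray(H)
    if H.size == 0:
        raise ValueError("empty hypernetwork")
    if include_diagonal:
        return float(H.mean())
    n = H.shape[0]
    if n < 2:
        raise ValueError("off-diagonal connectivity needs n_set >= 2")
    off = H[~np.eye(n, dtype=bool)]
    return float(off.mean())


def entropy_per_gene(H: np.ndarray) -> np.ndarray:
    """Shannon entropy (bits) of each gene's off-diagonal row profile.

    Each row's off-diagonal shared-relationship counts are normalised
    to a probability vector; a row of zeros has entropy 0 by
    convention. Values lie in [0, log2(n_set − 1)].
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    if n < 2:
        raise ValueError("entropy needs n_set >= 2")
    off = H[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    totals = off.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, off / totals, 0.0)
    logp = np.log2(p, out=np.zeros_like(p), where=p > 0)
    return -(p * logp).sum(axis=1)
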