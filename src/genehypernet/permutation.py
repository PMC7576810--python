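"""Randomised gene-set null for hypernetwork connectivity and entropy.

Whether an observed gene set is more connected, or more organised, than
chance is judged by rebuilding the hypernetwork many times from random
gene sets of the same size drawn from the filtered transcriptome, and
locating the observed statistic in the resulting null distribution
(add-one empirical p-value). Entropy distributions of two conditions
are compared with a two-sided Mann–Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .hypernetwork import manhattan_distance_matrix, binarise, build_hypernetwork


@dataclass
class NullDistribution:
    """Connectivity and median-entropy values from random gene sets."""

    connectivity_null: np.ndarray
    entropy_null: np.ndarray  # per-iteration median of the entropy vector
    n_iter: int
    set_size: int
    centile: float
    seed: int

    def p_connectivity(self, observed: float, tail: str = "greater") -> float:
        return empirical_p(observed, self.connectivity_null, tail)

    def p_entropy(self, observed_median: float, tail: str = "less") -> float:
        return empirical_p(observed_median, self.entropy_null, tail)


def null_distribution(
    matrix: ExpressionMatrix,
    condition_samples,
    set_size: int,
    n_iter: int = 1000,
    centile: float = 30.0,
    transform: str = "log2p1",
    include_diagonal: bool = True,
    seed: int = 0,
) -> NullDistribution:
    """Hypernetwork statistics of ``n_iter`` random gene sets.

    Each iteration draws ``set_size`` genes uniformly without
    replacement from all genes of ``matrix`` (the filtered
    transcriptome), rebuilds distance → incidence → hypernetwork over
    the given condition's samples, and records connectivity and the
    median per-gene entropy. Sub-seeds are derived deterministically
    from ``seed``, so a fixed seed reproduces the null bit-for-bit.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    gene_ids = matrix.gene_ids
    if set_size > len(gene_ids):
        raise ValueError(
            f"set_size {set_size} exceeds gene count {len(gene_ids)}"
        )
    if set_size < 2:
        raise ValueError("set_size must be >= 2")
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_iter)]
    conn = np.empty(n_iter)
    ent = np.empty(n_iter)
    gene_arr = np.asarray(gene_ids, dtype=object)
    for i, rng in enumerate(rngs):
        picked = gene_arr[rng.choice(len(gene_arr), size=set_size, replace=False)]
        dist = manhattan_distance_matrix(matrix, picked, condition_samples, transform)
        hn = build_hypernetwork(binarise(dist, centile), include_diagonal)
        conn[i] = hn.connectivity
        ent[i] = hn.median_entropy
    return NullDistribution(conn, ent, n_iter, set_size, centile, seed)


def empirical_p(observed: float, null, tail: str = "greater") -> float:
    """Add-one empirical p-value of ``observed`` against a null sample.

    p = (1 + #{null at least as extreme}) / (1 + len(null)); ties count
    as extreme, so p never reaches 0 and equals 1 when every null value
    is at least as extreme.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null vector")
    if tail == "greater":
        k = int((null >= observed).sum())
    elif tail == "less":
        k = int((null <= observed).sum())
    else:
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    return (1 + k) / (1 + null.size)


@dataclass
class EntropyComparison:
    """Two-sided rank comparison of two per-gene entropy vectors."""

    statistic: float
    p_value: float
    test: str
    median_a: float
    median_b: float


def compare_entropy(entropy_a, entropy_b) -> EntropyComparison:
    """Two-sided Mann–Whitney U test between two entropy vectors."""
    a = np.asarray(entropy_a, dtype=float)
    b = np.asarray(entropy_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each entropy vector needs >= 2 values")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return EntropyComparison(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test="mann-whitney-u",
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )
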