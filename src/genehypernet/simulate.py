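"""Synthetic multi-condition RNA-seq count matrices with ground truth.

The generator emulates the experimental design the analysis pipeline is
built for: a bulk transcriptome profiled under several transduction
conditions in biological triplicate, where each non-control condition
perturbs a small set of genes. Counts are negative binomial
(gamma–Poisson) around per-gene baselines; differential expression is a
condition-specific fold change on the mean; and a *coordinated* gene
set additionally shares a per-sample log-normal latent factor, so its
members co-vary across replicates the way a jointly regulated module
does, while an uncoordinated set responds with independent noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass(frozen=True)
class DESet:
    """One condition-specific differentially expressed gene set.

    ``log2fc_low``/``log2fc_high`` bound the |log2 fold change| drawn
    per gene (uniform); ``prop_up`` is the probability a gene is
    upregulated. ``coordination`` in [0, 1] sets the standard deviation
    of the shared per-sample latent factor on the natural-log scale:
    0 means members respond independently, values near 1 mean the whole
    module rises and falls together within each sample.
    """

    condition: str
    n_genes: int
    log2fc_low: float = 0.8
    log2fc_high: float = 2.0
    prop_up: float = 0.75
    coordination: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.coordination <= 1.0:
            raise ValueError("coordination must lie in [0, 1]")
        if self.log2fc_low < 0 or self.log2fc_high < self.log2fc_low:
            raise ValueError("require 0 <= log2fc_low <= log2fc_high")


def _default_de_sets() -> tuple[DESet, ...]:
    # A tightly coordinated module versus a diffusely regulated one of
    # the sizes the pipeline's downstream stages expect to handle.
    return (
        DESet("wt", 78, coordination=0.8),
        DESet("mutant", 106, coordination=0.0),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults describe a transcriptome-scale run (23766 genes, three
    conditions × three replicates); scale ``n_genes`` down for fast
    exploratory work. ``baseline_log_mean`` is the (mean, sd) of the
    per-gene log2 baseline expression; the default centres genes at a
    few hundred counts, the depth of a typical bulk 3'-tag library.
    ``dispersion`` is the negative
    binomial dispersion α in Var = μ + α·μ². Per-sample library sizes
    are drawn log-uniform on ``library_size_range`` so the
    normalisation stage is exercised.
    """

    n_genes: int = 23766
    conditions: tuple[str, ...] = ("wt", "mutant", "vector")
    n_replicates: int = 3
    baseline_log_mean: tuple[float, float] = (8.0, 2.0)
    dispersion: float = 0.1
    de_sets: tuple[DESet, ...] = field(default_factory=_default_de_sets)
    library_size_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ValueError("n_replicates must be positive")
        if len(self.conditions) < 1:
            raise ValueError("at least one condition required")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        total_de = sum(s.n_genes for s in self.de_sets)
        if total_de > self.n_genes:
            raise ValueError(
                f"de sets request {total_de} genes but only {self.n_genes} simulated"
            )
        unknown = [s.condition for s in self.de_sets if s.condition not in self.conditions]
        if unknown:
            raise ValueError(f"de set for unknown condition: {unknown}")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ValueError("library_size_range must be positive and ordered")


@dataclass
class GroundTruth:
    """Labels recording what the generator actually planted.

    ``de_genes`` maps each condition with a DE set to its gene ids;
    ``log2fc`` maps gene id to the planted signed log2 fold change;
    ``module_members`` lists, per condition, the genes sharing the
    latent coordination factor (all set members when coordination > 0).
    """

    de_genes: dict[str, list[str]]
    log2fc: dict[str, float]
    module_members: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "de_genes": self.de_genes,
            "log2fc": self.log2fc,
            "module_members": self.module_members,
        }


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw one count matrix plus its ground truth.

    The same ``config`` (including its seed) always yields bit-identical
    output. Counts are gamma–Poisson: per gene g and sample s,
    λ = μ_g · 2^{lfc(g, cond(s))} · F(s, module(g)) · L_s, with F the
    shared latent factor of g's module (1 outside the module's own
    condition) and L_s the library size factor.
    """
    rng = np.random.default_rng(config.seed)
    n_genes = config.n_genes
    samples = [
        f"{cond}_{r + 1}"
        for cond in config.conditions
        for r in range(config.n_replicates)
    ]
    cond_of = {
        s: s.rsplit("_", 1)[0] for s in samples
    }
    n_samples = len(samples)
    gene_ids = [f"G{i:06d}" for i in range(1, n_genes + 1)]

    mu_log2 = rng.normal(*config.baseline_log_mean, size=n_genes)
    mu0 = np.exp2(mu_log2)

    # disjoint DE gene indices across all sets
    total_de = sum(s.n_genes for s in config.de_sets)
    de_pool = rng.choice(n_genes, size=total_de, replace=False)
    offset = 0
    log2fc = np.zeros((n_genes, n_samples))
    latent = np.ones((n_genes, n_samples))
    truth_de: dict[str, list[str]] = {}
    truth_fc: dict[str, float] = {}
    truth_modules: dict[str, list[str]] = {}
    for de in config.de_sets:
        idx = de_pool[offset : offset + de.n_genes]
        offset += de.n_genes
        mags = rng.uniform(de.log2fc_low, de.log2fc_high, size=de.n_genes)
        signs = np.where(rng.random(de.n_genes) < de.prop_up, 1.0, -1.0)
        fc = mags * signs
        cols = [j for j, s in enumerate(samples) if cond_of[s] == de.condition]
        log2fc[np.ix_(idx, cols)] = fc[:, None]
        if de.coordination > 0:
            # one latent factor per sample of the set's own condition,
            # shared by every member; mean-one log-normal
            sigma = de.coordination
            z = rng.normal(0.0, sigma, size=len(cols))
            factor = np.exp(z - sigma**2 / 2.0)
            latent[np.ix_(idx, cols)] = factor[None, :]
            truth_modules[de.condition] = [gene_ids[i] for i in idx]
        else:
            truth_modules[de.condition] = []
        truth_de[de.condition] = [gene_ids[i] for i in idx]
        truth_fc.update({gene_ids[i]: float(f) for i, f in zip(idx, fc)})

    lo, hi = config.library_size_range
    lib = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_samples))

    mu = mu0[:, None] * np.exp2(log2fc) * latent * lib[None, :]
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam)

    df = pd.DataFrame(counts, index=gene_ids, columns=samples)
    em = ExpressionMatrix(df, cond_of, normalised=False)
    return em, GroundTruth(truth_de, truth_fc, truth_modules)
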