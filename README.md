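# genehypernet

Hypernetwork organisation analysis for differentially expressed (DE)
gene sets in bulk transcriptomes.

## The problem

Two perturbations can change similar numbers of genes yet differ
completely in how *coordinated* those changes are: one may drive a
tightly co-regulated programme, the other a diffuse scatter of
independent responses. Differential-expression lists alone cannot see
that difference. This package quantifies it with a hypernetwork: DE
genes are linked through the relationships they share with the rest of
the transcriptome, and the structure of those shared relationships is
summarised by connectivity and per-gene Shannon entropy.

It is aimed at transcriptomics analysts with a gene × sample count
matrix (conditions in replicate), who want to ask whether a gene set is
more organised — or more connected — than random sets of the same size.

## The method

Given normalised expression X (genes × samples) and a DE gene set
*S* of size *n* inside a transcriptome of *N* genes:

1. **Incidence matrix.** For each condition, compute the Manhattan
   (L1) distance d(i, j) = Σ_s |x_is − x_js| between every gene i ∈ S
   and every transcript j over that condition's replicate columns
   (log2(x+1) scale by default; a gene's self-column is masked).
   Binarise at the 30th centile of all distances: M_ij = 1 iff
   d(i, j) ≤ t, so only the closest relationships survive.
2. **Hypernetwork.** H = M·Mᵀ is the n × n matrix whose entry H_ij
   counts the transcripts that genes i and j are both close to.
   *Connectivity* is the mean entry of H. *Per-gene entropy* is the
   Shannon entropy (bits) of each row's off-diagonal profile,
   normalised to a probability vector: low entropy means a gene shares
   its neighbourhood with a concentrated subset of S, high entropy a
   diffuse one.
3. **Randomised null.** The same construction is repeated (default
   1000×) for random gene sets of size n drawn from the filtered
   transcriptome; add-one empirical p-values locate the observed
   connectivity and entropy in the null. Entropy distributions of two
   conditions are compared with a two-sided Mann–Whitney U test.

Upstream stages produce the DE sets: median-of-ratios size-factor
normalisation, a mean-expression filter (default 10), pairwise
contrasts against the control condition (Wald test on a fitted
negative-binomial mean–variance trend, Benjamini–Hochberg FDR,
|log2FC| > 0.6 and adjusted p < 0.05), a three-group ANOVA, and a
Venn-style partition into condition-exclusive, concordant and
discordant genes. The hypernetworks are built on the exclusive sets.

A negative-binomial simulator (`simulate_counts`) generates study-like
data — three conditions in triplicate, a coordinated DE module (shared
log-normal latent factor) versus a diffuse one — with ground-truth
labels, for power studies and end-to-end validation.

## Worked example

```python
import numpy as np
from genehypernet import *

em, truth = simulate_counts(SimulationConfig(n_genes=2000, seed=1))
filt = filter_expression(normalise(em), 10.0)

genes = [g for g in truth.de_genes["wt"] if g in filt.values.index]
dist = manhattan_distance_matrix(filt, genes, "wt")
inc  = binarise(dist, centile=30)
hn   = build_hypernetwork(inc)
null = null_distribution(filt, "wt", len(genes), n_iter=200, seed=1)

print(f"connectivity      : {hn.connectivity:.1f} "
      f"(null mean {null.connectivity_null.mean():.1f})")
print(f"median entropy    : {hn.median_entropy:.3f} bits "
      f"(max {np.log2(hn.n_set - 1):.3f})")
print(f"empirical p (conn): {null.p_connectivity(hn.connectivity):.4f}")

mut = [g for g in truth.de_genes["mutant"] if g in filt.values.index]
hn_mut = build_hypernetwork(
    binarise(manhattan_distance_matrix(filt, mut, "mutant"), 30))
res = compare_entropy(hn.entropy, hn_mut.entropy)
print(f"entropy wt vs mutant: medians {res.median_a:.3f} vs "
      f"{res.median_b:.3f}, MWU p = {res.p_value:.2e}")
```

prints

```
connectivity      : 210.3 (null mean 205.3)
median entropy    : 5.420 bits (max 6.267)
empirical p (conn): 0.2139
entropy wt vs mutant: medians 5.420 vs 5.733, MWU p = 8.03e-08
```

The coordinated 78-gene module (`wt`) has a lower median entropy than
the diffuse 106-gene set (`mutant`) — its genes share their
transcriptome relationships in a more organised way — and the
Mann–Whitney test confirms the separation of the two per-gene entropy
distributions. Its connectivity sits inside the random-set null here
(p = 0.21): organisation, not raw connectedness, is what distinguishes
this module at this scale.

## Command line

```sh
genehypernet simulate --n-genes 2000 --seed 11 --out-dir data/
genehypernet de --counts data/counts.tsv --samples data/samples.tsv \
    --contrast wt:vector --contrast mutant:vector --out-dir de/
genehypernet hypernet --matrix data/counts.tsv --samples data/samples.tsv \
    --condition wt --gene-set genes.txt --centile 30 --out-dir hn/
genehypernet null --matrix data/counts.tsv --samples data/samples.tsv \
    --condition wt --set-size 78 --iters 1000 --seed 42 --out-dir null/
genehypernet run --config run.toml      # the whole pipeline, one report
```

All results go to TSV/JSON files; logs go to stderr. A run's
`report.json` echoes the full configuration and seed, which reproduce
the report bit-for-bit (wall time aside).

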