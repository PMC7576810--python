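import numpy as np
import pandas as pd
import pytest

from genehypernet import ExpressionMatrix, SimulationConfig, DESet, simulate_counts


def make_matrix(values, conditions, gene_ids=None, normalised=False):
    """Small helper: build an ExpressionMatrix from a 2-D list/array.

    ``conditions`` is one label per column; sample ids are generated as
    ``<cond>_<k>``.
    """
    arr = np.asarray(values, dtype=float)
    counts = {}
    samples = []
    for c in conditions:
        counts[c] = counts.get(c, 0) + 1
        samples.append(f"{c}_{counts[c]}")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(arr.shape[0])]
    df = pd.DataFrame(arr, index=gene_ids, columns=samples)
    return ExpressionMatrix(df, dict(zip(samples, conditions)), normalised)


@pytest.fixture(scope="session")
def null_dataset():
    """Exchangeable simulated data: no DE genes, no coordination."""
    cfg = SimulationConfig(n_genes=2000, seed=7, de_sets=())
    em, truth = simulate_counts(cfg)
    return em, truth


@pytest.fixture(scope="session")
def study_dataset():
    """Default study design: coordinated 78-gene wt set, diffuse 106-gene set."""
    cfg = SimulationConfig(n_genes=2000, seed=11)
    em, truth = simulate_counts(cfg)
    return em, truth
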