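"""Gene × sample expression matrix with condition annotations."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A gene × sample numeric matrix with a condition label per sample.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample
        identifiers as columns. Entries are raw counts or normalised
        expression values, all non-negative.
    condition
        Mapping from sample id to condition label; every sample column
        must be covered.
    normalised
        True once library-size normalisation has been applied.
    """

    values: pd.DataFrame
    condition: dict[str, str] = field(default_factory=dict)
    normalised: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        missing = [s for s in cols if s not in self.condition]
        if missing:
            raise ValueError(f"samples without condition label: {missing[:5]}")
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be non-negative")

    # -- basic accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        seen: list[str] = []
        for s in self.values.columns:
            c = self.condition[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        """Sample ids belonging to one condition, in column order."""
        out = [s for s in self.values.columns if self.condition[s] == condition]
        if not out:
            known = sorted(set(self.condition.values()))
            raise KeyError(f"unknown condition {condition!r}; known: {known}")
        return out

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"unknown gene ids: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[gene_ids], dict(self.condition), self.normalised
        )

    def with_values(self, values: pd.DataFrame, normalised: bool | None = None) -> "ExpressionMatrix":
        """New matrix sharing this one's annotations."""
        cond = {s: self.condition[s] for s in values.columns}
        return ExpressionMatrix(
            values, cond, self.normalised if normalised is None else normalised
        )
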