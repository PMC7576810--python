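"""Readers and writers for the plain-text formats the pipeline uses.

Expression matrices travel as TSV (first column: gene id, header row:
sample ids), sample sheets as two-column TSV (sample_id, condition),
gene sets as one id per line, and summaries as JSON. Numeric values are
serialised at full precision so that a write/read round trip is exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


def read_sample_sheet(path) -> dict[str, str]:
    """Read a TSV mapping sample ids to condition labels.

    Expects columns ``sample_id`` and ``condition`` (header required).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"{path}: sample sheet lacks column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample id {dupes[0]!r}")
    return dict(zip(df["sample_id"], df["condition"]))


def write_sample_sheet(condition: dict[str, str], path) -> None:
    df = pd.DataFrame(
        {"sample_id": list(condition), "condition": list(condition.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, sample_sheet=None, condition=None) -> ExpressionMatrix:
    """Load a gene × sample TSV into an :class:`ExpressionMatrix`.

    Either ``sample_sheet`` (path to a TSV) or ``condition`` (a mapping)
    supplies the per-sample condition labels; if neither is given every
    sample is labelled ``"all"``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id {dupes[0]!r}")
    if df.columns.has_duplicates:
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample id {dupes[0]!r}")
    bad = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(bad):
        # locate the first offending cell for the error message
        col = bad[0]
        for line_no, v in enumerate(df[col], start=2):
            try:
                float(v)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric cell {v!r} in column {col!r}, line {line_no}"
                ) from None
        raise ValueError(f"{path}: non-numeric column {col!r}")
    if condition is None:
        if sample_sheet is not None:
            condition = read_sample_sheet(sample_sheet)
        else:
            condition = {s: "all" for s in df.columns}
    missing = [s for s in df.columns if s not in condition]
    if missing:
        raise ValueError(f"{path}: samples missing from sample sheet: {missing[:5]}")
    return ExpressionMatrix(df, {s: condition[s] for s in df.columns})


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_list(path) -> list[str]:
    """One gene id per line; blank lines and ``#`` comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(gene_ids, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
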