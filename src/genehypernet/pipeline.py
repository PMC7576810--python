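"""End-to-end pipeline: counts → DE sets → hypernetworks → nulls → report.

One configuration object drives the whole analysis so a run can be
reproduced bit-for-bit from its echoed config and seed: normalisation,
expression filtering, pairwise contrasts, the group ANOVA, the Venn
partition, per-condition hypernetworks on the exclusive DE sets, the
randomised gene-set nulls, and the entropy comparison between the two
conditions.
"""

from __future__ import annotations

import dataclasses
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .matrix import ExpressionMatrix
from .expression import (
    size_factors,
    normalise,
    filter_expression,
    de_pairwise,
    anova_groups,
    partition_gene_sets,
)
from .hypernetwork import manhattan_distance_matrix, binarise, build_hypernetwork
from .permutation import null_distribution, compare_entropy


class PipelineError(RuntimeError):
    """A stage precondition failed; the message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; defaults follow the analysis conventions.

    ``contrasts`` lists (condition, control) pairs; the first two
    conditions' exclusive DE sets feed the hypernetwork stage.
    """

    counts: str | None = None
    samples: str | None = None
    out_dir: str | None = None
    contrasts: tuple[tuple[str, str], ...] = (("wt", "vector"), ("mutant", "vector"))
    expression_threshold: float = 10.0
    fc_threshold: float = 0.6
    alpha: float = 0.05
    centile: float = 30.0
    n_iter: int = 1000
    transform: str = "log2p1"
    de_test: str = "nb"
    pseudocount: float = 1.0
    include_diagonal: bool = True
    per_row_centile: bool = False
    robust_anova: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.centile < 100:
            raise ValueError("centile must lie in (0, 100)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.expression_threshold < 0:
            raise ValueError("expression_threshold must be non-negative")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if len(self.contrasts) < 1:
            raise ValueError("at least one contrast required")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from a TOML file; tables are flattened into flat keys."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, val in raw.items():
            if isinstance(val, dict):
                flat.update(val)
            else:
                flat[key] = val
        if "contrasts" in flat:
            flat["contrasts"] = tuple(tuple(c) for c in flat["contrasts"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d


@dataclass
class RunReport:
    """Structured record of one pipeline run.

    Counts are internally consistent (exclusive + concordant +
    discordant = |union of significant sets|); the config echo plus
    seed suffice to reproduce every number except ``wall_time_s``.
    """

    config: dict
    version: str
    n_genes_input: int
    n_genes_filtered: int
    size_factors: dict[str, float]
    de: dict[str, dict]
    anova: dict | None
    partition: dict[str, int]
    hypernetworks: dict[str, dict]
    entropy_comparison: dict | None
    wall_time_s: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def validate(self) -> None:
        sizes = self.partition
        union = sum(sizes.values())
        n_sig = [v["n_significant"] for v in self.de.values()]
        if len(n_sig) >= 2:
            expected = (
                sizes["exclusive_a"]
                + sizes["exclusive_b"]
                + 2 * (sizes["concordant"] + sizes["discordant"])
            )
            if n_sig[0] + n_sig[1] != expected:
                raise AssertionError("partition sizes inconsistent with DE counts")
        if union < 0:  # pragma: no cover - arithmetic guard
            raise AssertionError


def _de_summary(de) -> dict:
    tab = de.table
    sig = tab["significant"]
    return {
        "comparison": de.comparison,
        "n_significant": int(sig.sum()),
        "n_up": int((sig & (tab["log2fc"] > 0)).sum()),
        "n_down": int((sig & (tab["log2fc"] < 0)).sum()),
    }


def run_pipeline(config: PipelineConfig, matrix: ExpressionMatrix | None = None) -> RunReport:
    """Execute every stage and return (and optionally write) the report.

    ``matrix`` bypasses file loading for programmatic use; otherwise
    ``config.counts`` and ``config.samples`` are read. With
    ``config.out_dir`` set, all stage outputs are written there as
    TSV/JSON.
    """
    from . import __version__

    t0 = time.monotonic()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"[{name}] {e}") from e
        return wrap

    if matrix is None:
        if config.counts is None or config.samples is None:
            raise PipelineError("[load] counts and samples paths are required")
        matrix = stage("load")(gio.read_expression_tsv, config.counts,
                               sample_sheet=config.samples)

    factors = stage("normalise")(size_factors, matrix)
    norm = stage("normalise")(normalise, matrix)
    filtered = stage("filter")(filter_expression, norm, config.expression_threshold)
    if filtered.n_genes < 2:
        raise PipelineError("[filter] fewer than 2 genes pass the expression filter")

    de_results = {}
    for cond, ctrl in config.contrasts:
        de_results[cond] = stage("de")(
            de_pairwise, filtered, cond, ctrl,
            fc_threshold=config.fc_threshold, alpha=config.alpha,
            pseudocount=config.pseudocount, test=config.de_test,
        )

    anova_summary = None
    if len(filtered.conditions) >= 3:
        anova_tab = stage("anova")(
            anova_groups, filtered, alpha=config.alpha,
            robust=config.robust_anova, pseudocount=config.pseudocount,
        )
        anova_summary = {
            "n_discriminating": int(anova_tab["discriminating"].sum()),
            "robust": config.robust_anova,
        }
        if out:
            anova_tab.to_csv(out / "anova.tsv", sep="\t", index_label="gene_id")

    conds = [c for c, _ in config.contrasts]
    first_two = conds[:2]
    partition = stage("partition")(
        partition_gene_sets, de_results[first_two[0]], de_results[first_two[1]]
    ) if len(conds) >= 2 else None

    exclusive_sets = {}
    if partition is not None:
        exclusive_sets[first_two[0]] = sorted(partition.exclusive_a)
        exclusive_sets[first_two[1]] = sorted(partition.exclusive_b)
    else:
        exclusive_sets[conds[0]] = sorted(de_results[conds[0]].significant_genes)

    hn_summaries: dict[str, dict] = {}
    hypernetworks = {}
    seed_seq = np.random.SeedSequence(config.seed)
    for k, (cond, gene_set) in enumerate(exclusive_sets.items()):
        if len(gene_set) < 2:
            hn_summaries[cond] = {"n_set": len(gene_set), "skipped": True}
            continue
        dist = stage("hypernetwork")(
            manhattan_distance_matrix, filtered, gene_set, cond, config.transform
        )
        inc = stage("hypernetwork")(binarise, dist, config.centile, config.per_row_centile)
        hn = stage("hypernetwork")(build_hypernetwork, inc, config.include_diagonal)
        null = stage("null")(
            null_distribution, filtered, cond, len(gene_set),
            n_iter=config.n_iter, centile=config.centile,
            transform=config.transform, include_diagonal=config.include_diagonal,
            seed=[config.seed, k],
        )
        hypernetworks[cond] = hn
        hn_summaries[cond] = {
            "n_set": hn.n_set,
            "n_total": dist.n_total,
            "centile": config.centile,
            "threshold": inc.threshold,
            "connectivity": hn.connectivity,
            "connectivity_no_diagonal": hn.connectivity_no_diagonal,
            "median_entropy": hn.median_entropy,
            "null_mean_connectivity": float(null.connectivity_null.mean()),
            "null_mean_median_entropy": float(null.entropy_null.mean()),
            "empirical_p_connectivity": null.p_connectivity(hn.connectivity),
            "empirical_p_entropy": null.p_entropy(hn.median_entropy),
            "n_iter": config.n_iter,
        }
        if out:
            pd.DataFrame(inc.values, index=inc.row_ids, columns=inc.col_ids).to_csv(
                out / f"incidence_{cond}.tsv", sep="\t", index_label="gene_id"
            )
            pd.DataFrame(hn.H, index=hn.gene_ids, columns=hn.gene_ids).to_csv(
                out / f"hypernetwork_{cond}.tsv", sep="\t", index_label="gene_id"
            )
            pd.DataFrame(
                {"connectivity": null.connectivity_null,
                 "median_entropy": null.entropy_null}
            ).to_csv(out / f"null_{cond}.tsv", sep="\t", index=False)
            gio.write_gene_list(gene_set, out / f"exclusive_{cond}.txt")

    ent_cmp = None
    if len(hypernetworks) >= 2:
        (ca, ha), (cb, hb) = list(hypernetworks.items())[:2]
        cmpres = stage("compare_entropy")(compare_entropy, ha.entropy, hb.entropy)
        ent_cmp = {
            "condition_a": ca,
            "condition_b": cb,
            "statistic": cmpres.statistic,
            "p_value": cmpres.p_value,
            "test": cmpres.test,
            "median_a": cmpres.median_a,
            "median_b": cmpres.median_b,
        }

    report = RunReport(
        config=config.echo(),
        version=__version__,
        n_genes_input=matrix.n_genes,
        n_genes_filtered=filtered.n_genes,
        size_factors={s: float(v) for s, v in factors.items()},
        de={c: _de_summary(d) for c, d in de_results.items()},
        anova=anova_summary,
        partition=partition.sizes() if partition is not None else {},
        hypernetworks=hn_summaries,
        entropy_comparison=ent_cmp,
        wall_time_s=time.monotonic() - t0,
    )
    if partition is not None:
        report.validate()
    if out:
        for cond, de in de_results.items():
            de.table.to_csv(out / f"de_{cond}.tsv", sep="\t", index_label="gene_id")
        gio.write_json(report.to_dict(), out / "report.json")
    return report
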