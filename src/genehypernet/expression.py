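"""Normalisation, filtering, differential expression and set partitioning.

These are the upstream stages that produce the condition-exclusive DE
gene sets fed to the hypernetwork analysis: median-of-ratios size-factor
normalisation, a low-expression filter, pairwise contrasts against a
control condition (Welch t-test on log2 values with Benjamini–Hochberg
correction), a multi-group ANOVA, and the Venn-style partition of two
contrasts into exclusive / concordant / discordant gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix


def size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios (geometric) size factor per sample.

    The reference profile is the per-gene geometric mean across samples,
    restricted to genes with strictly positive counts everywhere; each
    sample's factor is the median ratio of its counts to the reference.
    Dividing each column by its factor removes depth differences.
    """
    arr = counts.values.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no reference genes: every gene has a zero count")
    ref = arr[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    log_factors = np.median(ratios, axis=0)
    # standardise to geometric mean 1 so normalisation is idempotent
    factors = np.exp(log_factors - log_factors.mean())
    return pd.Series(factors, index=counts.values.columns, name="size_factor")


def normalise(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each sample column by its median-of-ratios size factor."""
    factors = size_factors(counts)
    return counts.with_values(counts.values / factors, normalised=True)


def filter_expression(matrix: ExpressionMatrix, threshold: float = 10.0) -> ExpressionMatrix:
    """Keep genes whose mean expression in at least one condition reaches ``threshold``.

    This plays the role of the conventional low-expression (FPKM-style)
    cut-off: it is applied to whatever normalised scale the matrix is
    on, and a gene survives if any condition's replicate mean is at or
    above the threshold. Gene order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    vals = matrix.values
    keep = np.zeros(matrix.n_genes, dtype=bool)
    for cond in matrix.conditions:
        cols = matrix.samples_of(cond)
        keep |= vals[cols].mean(axis=1).to_numpy() >= threshold
    return matrix.with_values(vals.loc[keep])


@dataclass
class DEResult:
    """Per-gene statistics of one pairwise contrast.

    ``table`` has columns log2fc, p_raw, p_adj, significant, indexed by
    gene id; ``comparison`` labels the contrast (e.g. ``wt_vs_vector``).
    A gene is significant iff |log2fc| > fc_threshold and p_adj < alpha.
    """

    table: pd.DataFrame
    comparison: str
    fc_threshold: float
    alpha: float

    @property
    def significant_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["significant"]])

    def sign_of(self, gene: str) -> int:
        return int(np.sign(self.table.at[gene, "log2fc"]))


def _bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    return multipletests(p_raw, method="fdr_bh")[1]


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _squeeze_var(
    s2: np.ndarray, df: float, covariate: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Empirical-Bayes shrinkage of per-gene variances.

    Fits a scaled inverse-chi-square prior (d0, s0²) to the observed
    variances by matching moments of log s² and returns the posterior
    variances (d0·s0² + df·s²)/(d0 + df) together with the prior df d0
    (np.inf when the observed variances are consistent with a single
    common value). With ``covariate`` given (mean log-expression), the
    prior value s0² follows a lowess trend in the covariate instead of
    being constant, which absorbs the mean–variance relationship of
    count data. This is the standard moderated-t construction used for
    small-replicate expression data.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(np.where(ok, s2, np.nan))
    bias = special.digamma(df / 2.0) - np.log(df / 2.0)
    e = z - bias
    if covariate is not None and ok.sum() >= 10:
        fit = lowess(e[ok], covariate[ok], frac=0.5, it=3,
                     xvals=covariate, return_sorted=False)
        trend = np.asarray(fit, dtype=float)
        # fall back to the global mean where lowess extrapolated to NaN
        trend = np.where(np.isfinite(trend), trend, np.nanmean(e))
    else:
        trend = np.full_like(s2, np.nanmean(e))
    resid = e - trend
    e_var = np.nanvar(resid, ddof=1) - float(special.polygamma(1, df / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_2 = np.exp(trend + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(trend)
    if np.isinf(d0):
        post = np.where(ok, s0_2, s2)
    else:
        post = np.where(ok, (d0 * s0_2 + df * s2) / (d0 + df), s2)
    return post, d0


def _nb_trend_pvalues(
    matrix: ExpressionMatrix, cond_a: str, cond_b: str, pseudocount: float
) -> np.ndarray:
    """Wald test on a negative-binomial mean–variance trend.

    The per-gene variance on the normalised count scale is predicted
    from a lowess trend of pooled within-condition variances against
    mean expression (bias-corrected for the expectation of log chi²),
    giving each gene an effectively known variance — the shrinkage that
    makes 3-replicate designs testable. The Wald statistic is the
    pseudocounted log2 fold change over its delta-method standard
    error.
    """
    groups = [
        matrix.values[matrix.samples_of(c)].to_numpy(dtype=float)
        for c in matrix.conditions
    ]
    groups = [g for g in groups if g.shape[1] >= 2]
    ss = sum(g.var(axis=1, ddof=1) * (g.shape[1] - 1) for g in groups)
    df = sum(g.shape[1] - 1 for g in groups)
    if df < 2:
        raise ValueError("need residual degrees of freedom >= 2 for the variance trend")
    s2 = ss / df
    m = np.concatenate(groups, axis=1).mean(axis=1)
    ok = (m > 0) & (s2 > 0)
    if ok.sum() >= 10:
        # E[log(s2)] = log(sigma2) + digamma(df/2) - log(df/2)
        bias = float(special.digamma(df / 2.0) - np.log(df / 2.0))
        pred = lowess(
            np.log(s2[ok]) - bias,
            np.log(m[ok]),
            frac=0.4,
            it=3,
            xvals=np.log(np.clip(m, 1e-8, None)),
            return_sorted=False,
        )
        pred = np.where(np.isfinite(pred), pred, np.nanmean(np.log(s2[ok]) - bias))
        s2_trend = np.exp(pred)
    else:
        s2_trend = np.full_like(s2, s2[ok].mean() if ok.any() else 1.0)
    disp = np.clip((s2_trend - m) / np.clip(m, 1e-8, None) ** 2, 0.0, None)

    a = matrix.values[matrix.samples_of(cond_a)].to_numpy(dtype=float)
    b = matrix.values[matrix.samples_of(cond_b)].to_numpy(dtype=float)
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    c = pseudocount
    var_log_a = (ma + disp * ma**2) / a.shape[1] / np.clip(ma + c, 1e-8, None) ** 2
    var_log_b = (mb + disp * mb**2) / b.shape[1] / np.clip(mb + c, 1e-8, None) ** 2
    se = np.sqrt(var_log_a + var_log_b) / np.log(2)
    fc = np.log2(ma + c) - np.log2(mb + c)
    z = fc / np.clip(se, 1e-12, None)
    return 2.0 * stats.norm.sf(np.abs(z))


def de_pairwise(
    matrix: ExpressionMatrix,
    cond_a: str,
    cond_b: str,
    fc_threshold: float = 0.6,
    alpha: float = 0.05,
    pseudocount: float = 1.0,
    test: str = "nb",
) -> DEResult:
    """Pairwise differential expression of ``cond_a`` versus ``cond_b``.

    log2 fold change is log2((mean_a + c) / (mean_b + c)) on the
    normalised scale with pseudocount ``c``. The default per-gene test
    (``"nb"``) is a Wald test against a negative-binomial mean–variance
    trend fitted across all genes — the dispersion-sharing idea of
    DESeq2/edgeR in a lean form, which is what keeps 3-replicate
    designs powered. ``"moderated"`` selects an empirical-Bayes
    moderated t-test on log2(x + c) and ``"welch"`` a plain Welch
    t-test. All are corrected across genes by Benjamini–Hochberg.
    """
    a_cols = matrix.samples_of(cond_a)
    b_cols = matrix.samples_of(cond_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition (got {len(a_cols)} vs {len(b_cols)})"
        )
    a = matrix.values[a_cols].to_numpy(dtype=float)
    b = matrix.values[b_cols].to_numpy(dtype=float)
    c = pseudocount
    log2fc = np.log2(a.mean(axis=1) + c) - np.log2(b.mean(axis=1) + c)
    if test == "nb":
        p_raw = _nb_trend_pvalues(matrix, cond_a, cond_b, c)
    elif test == "welch":
        la, lb = np.log2(a + c), np.log2(b + c)
        p_raw = stats.ttest_ind(la, lb, axis=1, equal_var=False).pvalue
    elif test == "moderated":
        la, lb = np.log2(a + c), np.log2(b + c)
        na, nb = la.shape[1], lb.shape[1]
        df_resid = na + nb - 2
        s2 = (la.var(axis=1, ddof=1) * (na - 1) + lb.var(axis=1, ddof=1) * (nb - 1)) / df_resid
        mean_expr = np.concatenate([la, lb], axis=1).mean(axis=1)
        s2_post, d0 = _squeeze_var(s2, df_resid, covariate=mean_expr)
        se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_stat = (la.mean(axis=1) - lb.mean(axis=1)) / se
        df_total = df_resid + d0
        if np.isinf(df_total):
            p_raw = 2.0 * stats.norm.sf(np.abs(t_stat))
        else:
            p_raw = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    else:
        raise ValueError(f"unknown test {test!r}")
    # zero variance everywhere (constant gene) yields NaN; such genes
    # carry no evidence either way, so they get p = 1
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj = _bh_adjust(p_raw)
    significant = (np.abs(log2fc) > fc_threshold) & (p_adj < alpha)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": significant,
        },
        index=matrix.values.index,
    )
    return DEResult(table, f"{cond_a}_vs_{cond_b}", fc_threshold, alpha)


def anova_groups(
    matrix: ExpressionMatrix,
    conditions: list[str] | None = None,
    alpha: float = 0.05,
    robust: bool = False,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene one-way ANOVA across ≥ 3 conditions on log2(x + c).

    Returns a DataFrame with p_raw, p_adj (Benjamini–Hochberg) and a
    ``discriminating`` flag (p_adj < alpha). With ``robust=True`` the
    rank-based Kruskal–Wallis test replaces the F-test, for callers who
    want a median-style comparison free of normality assumptions.
    """
    if conditions is None:
        conditions = matrix.conditions
    if len(conditions) < 3:
        raise ValueError(f"group ANOVA needs >= 3 conditions, got {len(conditions)}")
    groups = []
    for cond in conditions:
        cols = matrix.samples_of(cond)
        if len(cols) < 2:
            raise ValueError(f"condition {cond!r} has < 2 replicates")
        groups.append(np.log2(matrix.values[cols].to_numpy(dtype=float) + pseudocount))
    if robust:
        def _kw(row_groups):
            try:
                return stats.kruskal(*row_groups).pvalue
            except ValueError:  # all values identical
                return 1.0

        p_raw = np.array(
            [_kw([g[i] for g in groups]) for i in range(matrix.n_genes)]
        )
    else:
        p_raw = stats.f_oneway(*groups, axis=1).pvalue
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
    p_adj = _bh_adjust(p_raw)
    return pd.DataFrame(
        {
            "p_raw": p_raw,
            "p_adj": p_adj,
            "discriminating": p_adj < alpha,
        },
        index=matrix.values.index,
    )


@dataclass
class GeneSetPartition:
    """Venn partition of two contrasts' significant genes.

    ``concordant`` genes are significant in both contrasts with the
    same fold-change sign; ``discordant`` in both with opposite signs;
    the exclusive sets in exactly one. The four sets are pairwise
    disjoint.
    """

    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]
    concordant: frozenset[str]
    discordant: frozenset[str]

    def sizes(self) -> dict[str, int]:
        return {
            "exclusive_a": len(self.exclusive_a),
            "exclusive_b": len(self.exclusive_b),
            "concordant": len(self.concordant),
            "discordant": len(self.discordant),
        }


def partition_gene_sets(de_a: DEResult, de_b: DEResult) -> GeneSetPartition:
    """Partition significant genes of two contrasts over one gene universe."""
    if set(de_a.table.index) != set(de_b.table.index):
        raise ValueError("contrasts cover different gene universes")
    sig_a = de_a.significant_genes
    sig_b = de_b.significant_genes
    both = sig_a & sig_b
    concordant = frozenset(g for g in both if de_a.sign_of(g) == de_b.sign_of(g))
    return GeneSetPartition(
        exclusive_a=frozenset(sig_a - sig_b),
        exclusive_b=frozenset(sig_b - sig_a),
        concordant=concordant,
        discordant=frozenset(both - concordant),
    )
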