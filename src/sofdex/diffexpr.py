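"""Negative-binomial differential expression for two-group contrasts.

A deliberately simple NB Wald pipeline: median-of-ratios size factors,
method-of-moments dispersion pooled over replicate groups, and a Wald test on
the log ratio of normalized group means. No empirical-Bayes shrinkage,
independent filtering, or outlier refitting — the downstream classifier
consumes (log2FC, padj) pairs and is agnostic to the producer.

Conventions: ``log2FC > 0`` means higher in the first (treated/mutant) group
of a contrast. Genes that are all-zero across both contrast groups are
excluded and carry no statistics; they do not count toward the number of
tests in the Benjamini–Hochberg adjustment.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LN2 = np.log(2.0)

DEFAULT_GROUP_COLS = ("genotype", "treatment", "time")


@dataclass
class DEResult:
    """Per-gene differential-expression statistics for one named contrast.

    ``table`` is indexed by gene_id with columns ``baseMean``,
    ``log2FoldChange``, ``lfcSE``, ``pvalue``, ``padj`` and the boolean
    ``excluded`` flag (all-zero genes; NaN statistics).
    """

    contrast: str
    table: pd.DataFrame

    def significant(self, alpha: float = 0.05) -> pd.Index:
        t = self.table
        return t.index[(t["padj"] < alpha) & ~t["excluded"]]


def median_of_ratios(counts: pd.DataFrame, *,
                     allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    The reference is the per-gene geometric mean over samples, computed on
    genes with no zero count; each sample's factor is the median over those
    genes of count/reference.

    With ``allow_pseudo_reference`` the reference for each gene is the
    geometric mean over its *positive* counts and the median is taken over
    positive ratios only — a fallback for sparse matrices where no gene is
    zero-free.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("empty count matrix")
    zero_free = (x > 0).all(axis=1)
    if zero_free.any():
        logref = np.log(x[zero_free]).mean(axis=1)
        ratios = np.log(x[zero_free]) - logref[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    elif allow_pseudo_reference:
        with np.errstate(divide="ignore"):
            logx = np.where(x > 0, np.log(x), np.nan)
        logref = np.nanmean(logx, axis=1)
        ratios = logx - logref[:, None]
        if np.isnan(ratios).all(axis=0).any():
            raise ValueError("a sample has no positive counts on usable genes")
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        raise ValueError(
            "no gene has positive counts in every sample; pass "
            "allow_pseudo_reference=True to use the positive-count fallback")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, design: pd.DataFrame, *,
                        size_factors: pd.Series | None = None,
                        group_cols=DEFAULT_GROUP_COLS,
                        alpha_min: float = 1e-8) -> pd.Series:
    """Method-of-moments NB dispersion per gene, pooled across groups.

    Within each replicate group the normalized counts give a moment estimate
    ``(var - mean) / mean^2``; estimates are pooled across groups weighted by
    their degrees of freedom and floored at ``alpha_min``. Genes whose pooled
    variance does not exceed the mean receive the floor.
    """
    if size_factors is None:
        size_factors = median_of_ratios(counts)
    norm = counts.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    sample_pos = {s: i for i, s in enumerate(counts.columns)}

    num = np.zeros(counts.shape[0])
    den = 0.0
    any_replicated = False
    for _, grp in design.groupby(list(group_cols), sort=False):
        idx = [sample_pos[s] for s in grp["sample_id"]]
        if len(idx) < 2:
            continue
        any_replicated = True
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            est = np.where(m > 0, (v - m) / np.maximum(m, 1e-300) ** 2, 0.0)
        num += w * est
        den += w
    if not any_replicated:
        raise ValueError("dispersion estimation needs >=2 replicates in some condition")
    alpha = np.maximum(num / den, alpha_min)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    NaN inputs propagate as NaN and are excluded from the number of tests m.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[valid] = adj
    return out


def _group_stats(norm: np.ndarray, sf: np.ndarray, idx: list,
                 alpha: np.ndarray):
    """Mean of normalized counts and delta-method variance of its log."""
    n = len(idx)
    q = norm[:, idx].mean(axis=1)
    # zero group mean: substitute half a normalized count so the log is finite
    q_eff = np.where(q > 0, q, 0.5 / n)
    inv_s = (1.0 / sf[idx]).sum()
    var_log = (inv_s / q_eff + n * alpha) / n**2
    return q, q_eff, var_log


def nb_wald_test(counts: pd.DataFrame, design: pd.DataFrame,
                 contrast, *, size_factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None,
                 name: str | None = None) -> DEResult:
    """Two-group NB Wald test.

    ``contrast`` is a pair ``(samples_A, samples_B)`` of sample-id lists; the
    reported ``log2FoldChange`` is log2(mean_A / mean_B) of normalized group
    means, so positive values mean higher in the first (treated/mutant)
    group. The Wald statistic uses the delta-method standard error of the
    log-ratio under Var = mu + alpha*mu^2.
    """
    samples_a, samples_b = list(contrast[0]), list(contrast[1])
    label = name or f"{len(samples_a)}v{len(samples_b)}"
    if not samples_a or not samples_b:
        raise ValueError(f"contrast {label!r} has an empty group")
    known = set(counts.columns)
    missing = [s for s in samples_a + samples_b if s not in known]
    if missing:
        raise ValueError(f"contrast {label!r}: unknown samples {missing}")

    if size_factors is None:
        size_factors = median_of_ratios(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design,
                                          size_factors=size_factors)
    sf = size_factors.reindex(counts.columns).to_numpy()
    alpha = dispersions.reindex(counts.index).to_numpy()
    norm = counts.to_numpy(dtype=float) / sf[None, :]
    pos = {s: i for i, s in enumerate(counts.columns)}
    ia = [pos[s] for s in samples_a]
    ib = [pos[s] for s in samples_b]

    raw = counts.to_numpy()
    excluded = raw[:, ia + ib].sum(axis=1) == 0

    qa, qa_eff, var_a = _group_stats(norm, sf, ia, alpha)
    qb, qb_eff, var_b = _group_stats(norm, sf, ib, alpha)

    log2fc = np.log2(qa_eff / qb_eff)
    se_ln = np.sqrt(var_a + var_b)
    z = np.log(qa_eff / qb_eff) / se_ln
    pval = 2.0 * stats.norm.sf(np.abs(z))
    base_mean = norm[:, ia + ib].mean(axis=1)

    for arr in (log2fc, pval, base_mean):
        arr[excluded] = np.nan
    se = se_ln / LN2
    se[excluded] = np.nan

    table = pd.DataFrame({
        "baseMean": base_mean,
        "log2FoldChange": log2fc,
        "lfcSE": se,
        "pvalue": pval,
        "padj": bh_adjust(pval),
        "excluded": excluded,
    }, index=counts.index)
    return DEResult(contrast=label, table=table)


# ---------------------------------------------------------------------------
# contrast builders for the study design
# ---------------------------------------------------------------------------

def time_contrast(design: pd.DataFrame, genotype: str, time: int):
    """Dex-treated samples at ``time`` vs t=0 ethanol, within one genotype."""
    a = design.loc[(design["genotype"] == genotype) & (design["time"] == time)
                   & (design["treatment"] == "dex"), "sample_id"].tolist()
    b = design.loc[(design["genotype"] == genotype) & (design["time"] == 0)
                   & (design["treatment"] == "ethanol"), "sample_id"].tolist()
    return a, b


def genotype_contrast(design: pd.DataFrame, mutant: str, reference: str = "wt"):
    """All samples of ``mutant`` vs all of ``reference``, pooled over time."""
    a = design.loc[design["genotype"] == mutant, "sample_id"].tolist()
    b = design.loc[design["genotype"] == reference, "sample_id"].tolist()
    return a, b
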