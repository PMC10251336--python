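"""Gene-set selection from paired fold changes between GR mutants.

The selection reproduces the robust-outlier scheme used to define the SoF
gene sets: at the 3-h time point, each gene contributes a point
(x = SoF log2FC, y = Ctrl log2FC); an ordinary least-squares line is fit over
genes whose dex response is significant in either mutant; bivariate outliers
are found by the minimum covariance determinant; outliers strictly *below*
the line (Ctrl response lower than predicted from SoF, i.e. preferentially
activated when RNA binding is lost) that are significant in the SoF sample
become ``sof_dexdep``; the mirror image above the line becomes
``sof_3h_rep``. Constitutive sets come from the time-pooled mutant-vs-wt
contrast. Labels are mutually exclusive, with the dex-dependent sets taking
priority.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResult
from .robust import MCDResult, fast_mcd


@dataclass
class RegressionLine:
    slope: float
    intercept: float
    n_genes_used: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fold_change_pairs(sof: DEResult, ctrl: DEResult) -> pd.DataFrame:
    """Join two dex-response DE tables into per-gene fold-change pairs.

    Returns a DataFrame indexed by gene_id with columns ``log2FC_sof``,
    ``padj_sof``, ``log2FC_ctrl``, ``padj_ctrl``; genes excluded in either
    contrast are dropped.
    """
    a, b = sof.table, ctrl.table
    keep = a.index[~a["excluded"]].intersection(b.index[~b["excluded"]])
    return pd.DataFrame({
        "log2FC_sof": a.loc[keep, "log2FoldChange"],
        "padj_sof": a.loc[keep, "padj"],
        "log2FC_ctrl": b.loc[keep, "log2FoldChange"],
        "padj_ctrl": b.loc[keep, "padj"],
    })


def _gated(pairs: pd.DataFrame, alpha: float) -> pd.Series:
    """Significance gate: padj < alpha in either sample (or both)."""
    return ((pairs["padj_sof"] < alpha).fillna(False)
            | (pairs["padj_ctrl"] < alpha).fillna(False))


def regression_fit(pairs: pd.DataFrame, alpha: float = 0.05) -> RegressionLine:
    """OLS of Ctrl on SoF log2 fold changes over significance-gated genes."""
    gate = _gated(pairs, alpha)
    sub = pairs.loc[gate]
    if len(sub) < 3:
        raise ValueError(f"only {len(sub)} genes pass the significance gate; "
                         "need at least 3 to fit the regression")
    x = sub["log2FC_sof"].to_numpy()
    y = sub["log2FC_ctrl"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    return RegressionLine(slope=float(slope), intercept=float(intercept),
                          n_genes_used=len(sub))


def mcd_outliers(points, *, support_fraction: float | None = None,
                 cutoff: float = 0.975, n_starts: int = 500,
                 random_state: int = 0) -> MCDResult:
    """Bivariate MCD outliers of fold-change pairs.

    Thin wrapper over :func:`sofdex.robust.fast_mcd`; ``support_fraction``
    maps to h = ceil(fraction * n), default floor((n + d + 1) / 2).
    """
    X = np.asarray(points, dtype=float)
    h = None
    if support_fraction is not None:
        if not 0.5 <= support_fraction <= 1.0:
            raise ValueError("support_fraction must lie in [0.5, 1]")
        h = int(np.ceil(support_fraction * len(X)))
    return fast_mcd(X, h=h, cutoff=cutoff, n_starts=n_starts,
                    random_state=random_state)


def _outlier_frame(pairs: pd.DataFrame, line: RegressionLine,
                   outlier_mask) -> pd.DataFrame:
    mask = np.asarray(outlier_mask, dtype=bool)
    if len(mask) != len(pairs):
        raise ValueError("outlier mask length does not match pairs")
    pred = line.predict(pairs["log2FC_sof"].to_numpy())
    return pairs.assign(outlier=mask,
                        below_line=pairs["log2FC_ctrl"].to_numpy() < pred,
                        above_line=pairs["log2FC_ctrl"].to_numpy() > pred)


def select_sof_dexdep(pairs: pd.DataFrame, line: RegressionLine,
                      outlier_mask, alpha: float = 0.05) -> list:
    """SoF-amplified dex-dependent genes.

    MCD outliers strictly below the regression line in the (SoF, Ctrl) plane
    whose dex response is significant in the SoF sample (alone or with Ctrl).
    """
    f = _outlier_frame(pairs, line, outlier_mask)
    sig = (f["padj_sof"] < alpha).fillna(False)
    return f.index[f["outlier"] & f["below_line"] & sig].tolist()


def select_sof_3h_rep(pairs: pd.DataFrame, line: RegressionLine,
                      outlier_mask, alpha: float = 0.05, *,
                      method: str = "outlier") -> list:
    """Genes with the higher fold change in the Ctrl mutant at 3 h.

    Default ``method="outlier"`` mirrors :func:`select_sof_dexdep` on the
    other side of the line (significance required in the Ctrl sample);
    ``method="threshold"`` drops the outlier requirement and selects every
    gated gene above the line.
    """
    f = _outlier_frame(pairs, line, outlier_mask)
    sig = (f["padj_ctrl"] < alpha).fillna(False)
    if method == "outlier":
        keep = f["outlier"] & f["above_line"] & sig
    elif method == "threshold":
        keep = f["above_line"] & sig
    else:
        raise ValueError(f"unknown method {method!r}")
    return f.index[keep].tolist()


def select_constitutive_sets(mutant_vs_wt: DEResult, alpha: float = 0.05, *,
                             exclude=(), wt_dex_response: DEResult | None = None):
    """Constitutively SoF-up (dex-independent) and SoF-down gene sets.

    ``sof_dexind``: padj < alpha and log2FC > 0 in the time-pooled SoF-vs-wt
    contrast, excluding genes already claimed by the dex-dependent sets
    (``exclude``). ``sof_const_rep``: padj < alpha and log2FC < 0. With
    ``wt_dex_response`` supplied, dex-independence additionally requires a
    non-significant dex response in wt (strictness flag, off by default).
    """
    t = mutant_vs_wt.table
    sig = (t["padj"] < alpha) & ~t["excluded"]
    up = t.index[sig & (t["log2FoldChange"] > 0)]
    down = t.index[sig & (t["log2FoldChange"] < 0)]
    claimed = set(exclude)
    dexind = [g for g in up if g not in claimed]
    if wt_dex_response is not None:
        wt = wt_dex_response.table
        quiet = set(wt.index[~(wt["padj"] < alpha) | wt["excluded"]])
        dexind = [g for g in dexind if g in quiet]
    const_rep = [g for g in down if g not in claimed and g not in set(dexind)]
    return dexind, const_rep


def assemble_labels(universe, sof_dexdep, sof_3h_rep, sof_dexind,
                    sof_const_rep) -> pd.Series:
    """Mutually exclusive per-gene labels, dex-dependent sets taking priority."""
    labels = pd.Series("background", index=pd.Index(universe, name="gene_id"))
    for name, genes in (("sof_dexdep", sof_dexdep), ("sof_3h_rep", sof_3h_rep),
                        ("sof_dexind", sof_dexind),
                        ("sof_const_rep", sof_const_rep)):
        free = [g for g in genes if labels.get(g, None) == "background"]
        labels.loc[free] = name
    return labels


def zscore_abundance(counts: pd.DataFrame, design: pd.DataFrame, gene_set, *,
                     size_factors: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene z-scored abundance over the time course, within genotype.

    Normalized counts are averaged over replicates per (genotype, time), then
    each gene's series across the time course is standardized to mean 0 and
    sample sd 1 (ddof=1) within each genotype. Genes with zero variance get
    z = 0 by convention. Columns are a (genotype, time) MultiIndex.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("empty gene set")
    if size_factors is None:
        from .diffexpr import median_of_ratios
        size_factors = median_of_ratios(counts)
    norm = counts.loc[genes] / size_factors.reindex(counts.columns)

    cols = {}
    for (geno, t), grp in design.groupby(["genotype", "time"], sort=True):
        cols[(geno, t)] = norm[grp["sample_id"].tolist()].mean(axis=1)
    wide = pd.DataFrame(cols)
    wide.columns = pd.MultiIndex.from_tuples(wide.columns,
                                             names=["genotype", "time"])
    out = {}
    for geno in wide.columns.get_level_values("genotype").unique():
        block = wide[geno]
        mu = block.mean(axis=1)
        sd = block.std(axis=1, ddof=1)
        z = block.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
        for t in block.columns:
            out[(geno, t)] = z[t]
    res = pd.DataFrame(out)
    res.columns = pd.MultiIndex.from_tuples(res.columns,
                                            names=["genotype", "time"])
    return res.sort_index(axis=1)


def mann_whitney(sample_a, sample_b, alternative: str = "two-sided"):
    """Mann–Whitney U with the exact null for small tie-free samples.

    Exact enumeration when both samples have n <= 20 and no ties occur;
    otherwise the tie-corrected normal approximation with continuity
    correction. Returns ``(U, p)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
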