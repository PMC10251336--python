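"""Chromosomal and regional enrichment of a gene set along the genome.

Both statistics use the hypergeometric upper tail: drawing the K set genes
from the N-gene universe, how surprising is observing >= k of them among the
m universe genes on a chromosome (or inside a window of consecutive genes)?
The regional scan evaluates every window of consecutive position-sorted
universe genes up to a length cap, adjusts across all tested windows by
Benjamini–Hochberg, and greedily reports non-overlapping significant regions
— a bounded-window stand-in for positional-gene-enrichment tools, which is
sufficient because only FDR-adjusted region p-values are consumed downstream.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .genome import GenomeModel


def _set_indicator(gene_set, universe: GenomeModel) -> np.ndarray:
    genes = universe.genes["gene_id"]
    member = genes.isin(set(gene_set)).to_numpy()
    unknown = set(gene_set) - set(genes)
    if unknown:
        raise ValueError(f"set genes outside the universe: "
                         f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}")
    return member


def chromosome_enrichment(gene_set, universe: GenomeModel) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment per chromosome, BH-adjusted.

    Returns a DataFrame with one row per chromosome: ``k`` set genes of the
    ``m`` universe genes on it, p = P(X >= k), and padj across chromosomes.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    member = _set_indicator(gene_set, universe)
    N = universe.n_genes
    K = int(member.sum())
    rows = []
    for chrom in universe.chrom_names:
        on = (universe.genes["chrom"] == chrom).to_numpy()
        m = int(on.sum())
        k = int(member[on].sum())
        p = float(stats.hypergeom.sf(k - 1, N, K, m)) if k > 0 else 1.0
        rows.append({"chrom": chrom, "k": k, "m": m, "K": K, "N": N, "p": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    return out


def positional_scan(gene_set, universe: GenomeModel, *,
                    max_region_genes: int = 100,
                    alpha: float = 0.05,
                    keep_all: bool = False) -> pd.DataFrame:
    """Scan for contiguous regions enriched in set genes.

    Every window of 1..``max_region_genes`` consecutive universe genes (TSS
    order within chromosome) is scored with the hypergeometric upper tail;
    BH adjustment runs over all tested windows; significant windows are then
    reported greedily in order of ascending padj (ties: smaller genomic span,
    then leftmost), discarding windows that overlap an already-reported one.

    Returns a DataFrame of regions: chrom, first/last gene index within the
    chromosome, genomic start/end (bp, half-open over the spanned TSSs),
    k, m, K, N, p, padj. With ``keep_all`` the full table of tested windows
    is returned instead (no alpha filter, no greedy overlap resolution) —
    useful for diagnostics and calibration checks.
    """
    gene_set = list(gene_set)
    member = _set_indicator(gene_set, universe)
    N = universe.n_genes
    K = int(member.sum())
    if N == 0 or K == 0:
        return _empty_regions()

    win_chrom, win_start, win_len, win_k = [], [], [], []
    for ci, chrom in enumerate(universe.chrom_names):
        on = np.flatnonzero((universe.genes["chrom"] == chrom).to_numpy())
        if len(on) == 0:
            continue
        ind = member[on].astype(int)
        csum = np.concatenate([[0], np.cumsum(ind)])
        n_chrom = len(on)
        for length in range(1, min(max_region_genes, n_chrom) + 1):
            ks = csum[length:] - csum[:-length]
            starts = np.arange(n_chrom - length + 1)
            win_chrom.append(np.full(len(starts), ci))
            win_start.append(starts)
            win_len.append(np.full(len(starts), length))
            win_k.append(ks)

    chrom_i = np.concatenate(win_chrom)
    start_i = np.concatenate(win_start)
    length = np.concatenate(win_len)
    k = np.concatenate(win_k)
    p = stats.hypergeom.sf(k - 1, N, K, length)
    p = np.where(k > 0, p, 1.0)
    padj = bh_adjust(p)

    tss = universe.genes["tss"].to_numpy()
    chrom_offsets = {
        ci: np.flatnonzero((universe.genes["chrom"] == chrom).to_numpy())
        for ci, chrom in enumerate(universe.chrom_names)}

    if keep_all:
        rows = []
        for w in range(len(p)):
            ci, s, l = int(chrom_i[w]), int(start_i[w]), int(length[w])
            on = chrom_offsets[ci]
            rows.append({
                "chrom": universe.chrom_names[ci],
                "first_gene_index": s, "last_gene_index": s + l - 1,
                "start": int(tss[on[s]]), "end": int(tss[on[s + l - 1]]) + 1,
                "k": int(k[w]), "m": l, "K": K, "N": N,
                "p": float(p[w]), "padj": float(padj[w]),
            })
        return pd.DataFrame(rows)

    sig = np.flatnonzero((padj < alpha) & (k > 0))
    if sig.size == 0:
        return _empty_regions()

    span_bp = np.empty(sig.size)
    for i, w in enumerate(sig):
        on = chrom_offsets[chrom_i[w]]
        lo = tss[on[start_i[w]]]
        hi = tss[on[start_i[w] + length[w] - 1]]
        span_bp[i] = hi - lo + 1

    order = sig[np.lexsort((start_i[sig], chrom_i[sig], span_bp, padj[sig]))]
    taken: dict = {}
    rows = []
    for w in order:
        ci, s, l = int(chrom_i[w]), int(start_i[w]), int(length[w])
        intervals = taken.setdefault(ci, [])
        if any(s < e0 and s0 < s + l for s0, e0 in intervals):
            continue
        intervals.append((s, s + l))
        on = chrom_offsets[ci]
        rows.append({
            "chrom": universe.chrom_names[ci],
            "first_gene_index": s,
            "last_gene_index": s + l - 1,
            "start": int(tss[on[s]]),
            "end": int(tss[on[s + l - 1]]) + 1,
            "k": int(k[w]), "m": l, "K": K, "N": N,
            "p": float(p[w]), "padj": float(padj[w]),
        })
    return pd.DataFrame(rows)


def _empty_regions() -> pd.DataFrame:
    return pd.DataFrame(columns=["chrom", "first_gene_index", "last_gene_index",
                                 "start", "end", "k", "m", "K", "N",
                                 "p", "padj"])
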