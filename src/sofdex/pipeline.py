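"""End-to-end pipeline: simulate -> DE -> classify -> co-occur -> positional.

Every run writes all stage artifacts plus a JSON summary into a run
directory; the summary embeds a manifest of all parameters and seeds, and —
because the inputs here are simulated with known truth — sensitivity/FDR of
each recovered gene set against the planted labels.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, cooccurrence, diffexpr, io, positional
from .genome import set_recovery
from .synthetic import SimulationParams, simulate_chip_peaks, simulate_counts, \
    simulate_genome

log = logging.getLogger("sofdex")


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    seed: int = 0
    alpha: float = 0.05
    window: int = 30_000
    classify_time: int = 3
    n_shuffles: int = 100
    p_near: float = 0.8
    n_background_peaks: int = 500
    max_region_genes: int = 100
    sim: SimulationParams = field(default_factory=SimulationParams)

    def __post_init__(self) -> None:
        # one seed drives every stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        for key in ("dex_profile", "dex_max_log2fc_range", "cluster_chromosomes",
                    "libsize_log2_range"):
            if key in sim and isinstance(sim[key], list):
                sim[key] = tuple(sim[key])
        return cls(sim=SimulationParams(**sim), **d)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done", name)
            return out
        return inner
    return wrap


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full analysis on simulated data and write all artifacts.

    Returns the JSON-serializable summary (also written to ``summary.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------------
    genome, truth = _stage("simulate_genome")(simulate_genome)(config.sim)
    counts, design = _stage("simulate_counts")(simulate_counts)(
        genome, truth, config.sim)
    peaks = _stage("simulate_peaks")(simulate_chip_peaks)(
        genome, truth, p_near=config.p_near, window=config.window,
        n_background=config.n_background_peaks, seed=config.seed)

    io.write_chrom_sizes(genome.chrom_sizes, out / "chrom.sizes")
    io.write_tss(genome.genes, out / "tss.tsv")
    truth.labels.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
    io.write_counts(counts, out / "counts.tsv")
    io.write_design(design, out / "design.tsv")
    io.write_bed(peaks, out / "peaks.bed")
    log.info("simulated %d genes, %d samples, %d peaks",
             genome.n_genes, len(design), len(peaks))

    # --- differential expression -------------------------------------------
    size_factors = diffexpr.median_of_ratios(counts)
    dispersions = diffexpr.estimate_dispersion(counts, design,
                                               size_factors=size_factors)
    size_factors.to_csv(out / "size_factors.tsv", sep="\t")

    de = {}
    t = config.classify_time
    for genotype in ("wt", "SoF", "Ctrl"):
        name = f"{genotype}_t{t}_vs_t0"
        de[name] = diffexpr.nb_wald_test(
            counts, design, diffexpr.time_contrast(design, genotype, t),
            size_factors=size_factors, dispersions=dispersions, name=name)
    de["SoF_vs_wt"] = diffexpr.nb_wald_test(
        counts, design, diffexpr.genotype_contrast(design, "SoF"),
        size_factors=size_factors, dispersions=dispersions, name="SoF_vs_wt")
    for name, res in de.items():
        res.table.to_csv(out / f"de_{name}.tsv", sep="\t")

    # --- gene-set classification -------------------------------------------
    pairs = classify.fold_change_pairs(de[f"SoF_t{t}_vs_t0"],
                                       de[f"Ctrl_t{t}_vs_t0"])
    gate = (pairs["padj_sof"] < config.alpha).fillna(False) | \
           (pairs["padj_ctrl"] < config.alpha).fillna(False)
    gated = pairs.loc[gate]
    line = classify.regression_fit(pairs, config.alpha)
    mcd = classify.mcd_outliers(
        gated[["log2FC_sof", "log2FC_ctrl"]].to_numpy(),
        random_state=config.seed)
    sof_dexdep = classify.select_sof_dexdep(gated, line, mcd.outliers,
                                            config.alpha)
    sof_3h_rep = classify.select_sof_3h_rep(gated, line, mcd.outliers,
                                            config.alpha)
    sof_dexind, sof_const_rep = classify.select_constitutive_sets(
        de["SoF_vs_wt"], config.alpha, exclude=sof_dexdep + sof_3h_rep)
    labels = classify.assemble_labels(counts.index, sof_dexdep, sof_3h_rep,
                                      sof_dexind, sof_const_rep)
    labels.rename("label").to_csv(out / "gene_set_labels.tsv", sep="\t")

    # --- co-occurrence ------------------------------------------------------
    tss = genome.tss_table()
    sets_of_interest = {
        "sof_dexdep": sof_dexdep,
        "sof_dexind": sof_dexind,
        "direct_targets_truth": truth.genes_in_class("direct_dex")
                                + truth.genes_in_class("sof_dexdep"),
    }
    cooccur = {}
    rng = np.random.default_rng(config.seed)
    for set_name, genes in sets_of_interest.items():
        sub = tss[tss["gene_id"].isin(set(genes))]
        if len(sub) == 0:
            cooccur[set_name] = {"n": 0}
            continue
        ratio, _ = cooccurrence.window_overlap_ratio(sub, peaks, config.window)
        rel = cooccurrence.relative_distance(sub, peaks)
        rel.histogram.to_csv(out / f"reldist_{set_name}.tsv", sep="\t",
                             index=False)
        shuffled = []
        for i in range(config.n_shuffles):
            shuf = cooccurrence.shuffle_tss(sub, genome.chrom_sizes,
                                            seed=int(rng.integers(2**31)))
            r, _ = cooccurrence.window_overlap_ratio(shuf, peaks, config.window)
            shuffled.append(r)
        cooccur[set_name] = {
            "n": len(sub),
            "window_overlap_ratio": ratio,
            "shuffled_ratio_mean": float(np.mean(shuffled)),
            "shuffled_ratio_sd": float(np.std(shuffled, ddof=1)),
            "mean_relative_distance": float(rel.values.mean())
                if len(rel.values) else None,
            "n_reldist_skipped": rel.n_skipped,
        }

    # --- positional enrichment ---------------------------------------------
    chrom_table = positional.chromosome_enrichment(sof_dexind, genome) \
        if sof_dexind else pd.DataFrame()
    regions = positional.positional_scan(sof_dexind, genome,
                                         max_region_genes=config.max_region_genes,
                                         alpha=config.alpha)
    chrom_table.to_csv(out / "chromosome_enrichment.tsv", sep="\t", index=False)
    regions.to_csv(out / "enriched_regions.tsv", sep="\t", index=False)

    # --- summary ------------------------------------------------------------
    recovery = {
        name: set_recovery(pred, truth.genes_in_class(name))
        for name, pred in (("sof_dexdep", sof_dexdep),
                           ("sof_3h_rep", sof_3h_rep),
                           ("sof_dexind", sof_dexind),
                           ("sof_const_rep", sof_const_rep))
    }
    summary = {
        "manifest": config.to_dict(),
        "n_genes": genome.n_genes,
        "n_samples": len(design),
        "n_peaks": len(peaks),
        "regression_line": {"slope": line.slope, "intercept": line.intercept,
                            "n_genes_used": line.n_genes_used},
        "mcd": {"h": mcd.h, "cutoff": mcd.cutoff,
                "n_points": int(len(gated)),
                "n_outliers": int(mcd.outliers.sum())},
        "set_sizes": {"sof_dexdep": len(sof_dexdep),
                      "sof_3h_rep": len(sof_3h_rep),
                      "sof_dexind": len(sof_dexind),
                      "sof_const_rep": len(sof_const_rep)},
        "recovery": recovery,
        "cooccurrence": cooccur,
        "positional": {
            "n_regions": int(len(regions)),
            "enriched_chromosomes": chrom_table.loc[
                chrom_table["padj"] < config.alpha, "chrom"].tolist()
                if len(chrom_table) else [],
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return summary
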