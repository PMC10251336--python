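"""Genome coordinate model shared by simulation and interval statistics.

All coordinates are 0-based; intervals are half-open ``[start, end)`` as in
BED; a TSS is a single 0-based position (the starting nucleotide of the gene
body). Chromosome order is the order of ``chrom_sizes`` and is preserved by
every operation that sorts genomic records.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Gene classes carried by simulation truth labels and by the classifier.
#: ``direct_dex``  — dexamethasone-activated in every genotype;
#: ``sof_dexdep``  — dex-activated with amplified response in the SoF genotype;
#: ``sof_3h_rep``  — dex-activated but attenuated in the SoF genotype;
#: ``sof_dexind``  — constitutively up in SoF at all times including t=0;
#: ``sof_const_rep`` — constitutively down in SoF.
GENE_CLASSES = (
    "background",
    "direct_dex",
    "sof_dexdep",
    "sof_3h_rep",
    "sof_dexind",
    "sof_const_rep",
)

GENE_COLUMNS = ("gene_id", "chrom", "tss", "strand")


@dataclass(frozen=True)
class GenomeModel:
    """A set of named chromosomes and point-TSS genes placed on them.

    Parameters
    ----------
    chrom_sizes
        Mapping chromosome name -> length in bp; iteration order defines
        genome order.
    genes
        DataFrame with columns ``gene_id, chrom, tss, strand``, sorted by
        genome order then TSS.
    """

    chrom_sizes: dict
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(GENE_COLUMNS) - set(self.genes.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        for name, size in self.chrom_sizes.items():
            if int(size) <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {size}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise ValueError(f"duplicate gene_id {dup!r}")
        unknown = set(self.genes["chrom"]) - set(self.chrom_sizes)
        if unknown:
            raise ValueError(f"genes on unknown chromosomes: {sorted(unknown)}")
        if len(self.genes):
            sizes = self.genes["chrom"].map(self.chrom_sizes).to_numpy()
            tss = self.genes["tss"].to_numpy()
            if (tss < 0).any() or (tss >= sizes).any():
                bad = self.genes.loc[(tss < 0) | (tss >= sizes), "gene_id"].iloc[0]
                raise ValueError(f"TSS of gene {bad!r} outside chromosome bounds")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def chrom_names(self) -> list:
        return list(self.chrom_sizes)

    def tss_table(self) -> pd.DataFrame:
        """The gene table restricted to TSS columns (gene_id, chrom, tss)."""
        return self.genes[["gene_id", "chrom", "tss"]].copy()


@dataclass(frozen=True)
class TruthLabels:
    """Per-gene simulation ground truth.

    ``labels`` has columns ``gene_id, label, cluster_id``; ``cluster_id`` is
    -1 except for spatially clustered dex-independent genes, where it indexes
    the planted run the gene belongs to.
    """

    labels: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "label", "cluster_id"}
        missing = required - set(self.labels.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        bad = set(self.labels["label"]) - set(GENE_CLASSES)
        if bad:
            raise ValueError(f"unknown gene classes: {sorted(bad)}")
        if self.labels["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id in truth labels")

    def genes_in_class(self, label: str) -> list:
        if label not in GENE_CLASSES:
            raise ValueError(f"unknown class {label!r}")
        mask = self.labels["label"] == label
        return self.labels.loc[mask, "gene_id"].tolist()

    def class_of(self) -> pd.Series:
        """gene_id-indexed Series of class labels."""
        return self.labels.set_index("gene_id")["label"]


def sort_genomic(df: pd.DataFrame, chrom_order, pos_col: str = "start") -> pd.DataFrame:
    """Sort a genomic record table by genome order then position."""
    order = {name: i for i, name in enumerate(chrom_order)}
    key = df["chrom"].map(order)
    if key.isna().any():
        unknown = sorted(set(df.loc[key.isna(), "chrom"]))
        raise ValueError(f"records on unknown chromosomes: {unknown}")
    out = df.assign(_k=key).sort_values(["_k", pos_col], kind="mergesort")
    return out.drop(columns="_k").reset_index(drop=True)


def set_recovery(predicted, truth_genes) -> dict:
    """Sensitivity and empirical FDR of a predicted gene set vs planted truth."""
    pred = set(predicted)
    true = set(truth_genes)
    tp = len(pred & true)
    sens = tp / len(true) if true else np.nan
    fdr = (len(pred) - tp) / len(pred) if pred else 0.0
    return {"n_predicted": len(pred), "n_true": len(true),
            "sensitivity": sens, "fdr": fdr}
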