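"""Readers and writers for the plain-text exchange formats.

Internal coordinates are uniformly 0-based half-open; BED is read and
written as-is (it shares the convention). Malformed lines are reported with
their 1-based line number.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

DESIGN_COLUMNS = ("sample_id", "genotype", "treatment", "time", "replicate")


def read_chrom_sizes(path) -> dict:
    """Two-column TSV (chrom, length) -> ordered dict."""
    sizes = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated "
                             f"fields, got {len(fields)}")
        name = fields[0]
        try:
            size = int(fields[1])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer length "
                             f"{fields[1]!r}") from None
        if size <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive length {size}")
        if name in sizes:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {name!r}")
        sizes[name] = size
    return sizes


def write_chrom_sizes(sizes: dict, path) -> None:
    with open(path, "w") as fh:
        for name, size in sizes.items():
            fh.write(f"{name}\t{size}\n")


def read_bed(path, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """BED (>= 3 columns, tab-separated, 0-based half-open) -> DataFrame.

    Validates start < end (and end <= chromosome length when sizes are
    given); errors name the offending line.
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >=3 tab-separated "
                             f"columns, got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates "
                             f"{fields[1]!r}/{fields[2]!r}") from None
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{lineno}: invalid interval "
                             f"[{start}, {end})")
        if chrom_sizes is not None:
            if chrom not in chrom_sizes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome "
                                 f"{chrom!r}")
            if end > chrom_sizes[chrom]:
                raise ValueError(f"{path}:{lineno}: end {end} exceeds "
                                 f"{chrom!r} length {chrom_sizes[chrom]}")
        row = {"chrom": chrom, "start": start, "end": end}
        if len(fields) > 3:
            row["name"] = fields[3]
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]
                        if any("name" in r for r in rows)
                        else ["chrom", "start", "end"])


def write_bed(df: pd.DataFrame, path) -> None:
    cols = ["chrom", "start", "end"] + (["name"] if "name" in df.columns else [])
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_counts(path) -> pd.DataFrame:
    """Counts TSV (gene_id + one integer column per sample) -> DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    for col in df.columns:
        vals = df[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            as_float = vals.astype(float)
            if not np.all(as_float == np.floor(as_float)):
                bad = df.index[as_float != np.floor(as_float)][0]
                raise ValueError(f"{path}: non-integer count at gene "
                                 f"{bad!r}, sample {col!r}")
            df[col] = as_float.astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative counts present")
    df.index.name = "gene_id"
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DESIGN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: design missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicated sample id {dup!r}")
    return df


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_tss(path, chrom_sizes: dict | None = None) -> pd.DataFrame:
    """TSS TSV (gene_id, chrom, tss[, strand]) -> DataFrame."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "chrom", "tss"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: TSS table missing columns {sorted(missing)}")
    if chrom_sizes is not None:
        for i, row in df.iterrows():
            if row["chrom"] not in chrom_sizes:
                raise ValueError(f"{path}: row {i + 2}: unknown chromosome "
                                 f"{row['chrom']!r}")
            if not 0 <= row["tss"] < chrom_sizes[row["chrom"]]:
                raise ValueError(f"{path}: row {i + 2}: TSS {row['tss']} out "
                                 f"of bounds for {row['chrom']!r}")
    return df


def write_tss(tss: pd.DataFrame, path) -> None:
    tss.to_csv(path, sep="\t", index=False)


def read_cq(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "condition", "gene", "cq"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Cq table missing columns {sorted(missing)}")
    return df
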