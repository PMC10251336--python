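"""Spatial association between gene TSSs and ChIP peak intervals.

Statistics follow the bedtools conventions the field uses: intervals are
0-based half-open; the relative-distance statistic reduces peaks to
midpoints and is Uniform[0, 0.5] when TSSs are placed independently of
peaks; the windowed overlap ratio counts a TSS if any peak interval comes
within ``window`` bp of it; the shuffle null re-places TSSs uniformly over
the genome (chromosomes weighted by length).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _require_columns(df: pd.DataFrame, cols, what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{what} table missing columns: {sorted(missing)}")


def merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Union of intervals on one chromosome, as sorted disjoint arrays."""
    order = np.argsort(starts, kind="mergesort")
    s, e = starts[order], ends[order]
    out_s, out_e = [], []
    for i in range(len(s)):
        if out_e and s[i] <= out_e[-1]:
            out_e[-1] = max(out_e[-1], e[i])
        else:
            out_s.append(s[i])
            out_e.append(e[i])
    return np.asarray(out_s), np.asarray(out_e)


def intersect_peaks(set_a: pd.DataFrame, set_b: pd.DataFrame, *,
                    chrom_names=None) -> pd.DataFrame:
    """Members of A overlapping at least 1 bp of B (half-open semantics).

    ``[s1, e1)`` overlaps ``[s2, e2)`` iff ``s1 < e2 and s2 < e1``; abutting
    intervals do not overlap. Output preserves A's records and order. With
    ``chrom_names`` given, chromosomes outside that namespace raise.
    """
    for df, what in ((set_a, "peak set A"), (set_b, "peak set B")):
        _require_columns(df, ("chrom", "start", "end"), what)
        if len(df) and (df["start"].to_numpy() >= df["end"].to_numpy()).any():
            raise ValueError(f"{what} has intervals with start >= end")
        if chrom_names is not None:
            unknown = set(df["chrom"]) - set(chrom_names)
            if unknown:
                raise ValueError(
                    f"{what} has unknown chromosomes: {sorted(unknown)}")

    keep = np.zeros(len(set_a), dtype=bool)
    b_by_chrom = {c: g for c, g in set_b.groupby("chrom", sort=False)}
    for chrom, grp in set_a.groupby("chrom", sort=False):
        if chrom not in b_by_chrom:
            continue
        b = b_by_chrom[chrom]
        ms, me = merge_intervals(b["start"].to_numpy(), b["end"].to_numpy())
        s1 = grp["start"].to_numpy()
        e1 = grp["end"].to_numpy()
        # merged B is disjoint & sorted: the only candidate is the last
        # merged interval starting before e1
        j = np.searchsorted(ms, e1, side="left") - 1
        valid = j >= 0
        hit = np.zeros(len(grp), dtype=bool)
        hit[valid] = me[j[valid]] > s1[valid]
        keep[np.flatnonzero(set_a["chrom"].to_numpy() == chrom)] = hit
    return set_a.loc[keep].copy()


@dataclass
class RelativeDistanceResult:
    values: pd.Series          # gene_id -> relative distance in [0, 0.5]
    n_skipped: int             # TSSs without flanking peaks on both sides
    histogram: pd.DataFrame    # bin_left, bin_right, count, frequency


def relative_distance(tss: pd.DataFrame, peaks: pd.DataFrame,
                      nbins: int = 25) -> RelativeDistanceResult:
    """Relative distance of each TSS to its flanking peak midpoints.

    For a TSS t between consecutive peak midpoints L < R the value is
    ``min(t - L, R - t) / (R - L)``; TSSs outside the outermost midpoints of
    their chromosome are skipped and counted (no circularization).
    Chromosomes with fewer than two peaks contribute only skips (warning).
    """
    _require_columns(tss, ("gene_id", "chrom", "tss"), "TSS")
    _require_columns(peaks, ("chrom", "start", "end"), "peak")
    values = {}
    n_skipped = 0
    mids_by_chrom = {
        c: np.sort((g["start"].to_numpy() + g["end"].to_numpy()) / 2.0)
        for c, g in peaks.groupby("chrom", sort=False)}
    for chrom, grp in tss.groupby("chrom", sort=False):
        mids = mids_by_chrom.get(chrom, np.empty(0))
        if len(mids) < 2:
            warnings.warn(f"chromosome {chrom!r} has {len(mids)} peak(s); "
                          f"skipping its {len(grp)} TSS(s)")
            n_skipped += len(grp)
            continue
        t = grp["tss"].to_numpy(dtype=float)
        inside = (t >= mids[0]) & (t <= mids[-1])
        n_skipped += int((~inside).sum())
        ti = t[inside]
        right = np.searchsorted(mids, ti, side="left")
        right = np.clip(right, 1, len(mids) - 1)
        L, R = mids[right - 1], mids[right]
        rel = np.minimum(ti - L, R - ti) / (R - L)
        for gid, v in zip(grp.loc[inside, "gene_id"], rel):
            values[gid] = v

    vals = pd.Series(values, name="relative_distance", dtype=float)
    edges = np.linspace(0.0, 0.5, nbins + 1)
    count, _ = np.histogram(vals.to_numpy(), bins=edges)
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": count,
                         "frequency": count / max(len(vals), 1)})
    return RelativeDistanceResult(values=vals, n_skipped=n_skipped,
                                  histogram=hist)


def distance_to_nearest_peak(tss: pd.DataFrame,
                             peaks: pd.DataFrame) -> pd.Series:
    """bp distance from each TSS to the nearest peak interval.

    0 if the point lies inside an interval; otherwise the gap in bases to
    the nearest included base of the half-open interval. TSSs on chromosomes
    without peaks get +inf.
    """
    _require_columns(tss, ("gene_id", "chrom", "tss"), "TSS")
    _require_columns(peaks, ("chrom", "start", "end"), "peak")
    out = pd.Series(np.inf, index=pd.Index(tss["gene_id"], name="gene_id"),
                    name="distance")
    by_chrom = {c: merge_intervals(g["start"].to_numpy(), g["end"].to_numpy())
                for c, g in peaks.groupby("chrom", sort=False)}
    for chrom, grp in tss.groupby("chrom", sort=False):
        if chrom not in by_chrom:
            continue
        ms, me = by_chrom[chrom]
        t = grp["tss"].to_numpy(dtype=float)
        j = np.searchsorted(ms, t, side="right") - 1
        dist = np.full(len(t), np.inf)
        valid = j >= 0
        inside = valid & (t < me[np.clip(j, 0, None)])
        dist[inside] = 0.0
        # gap to the interval on the left: last included base is me-1
        left_gap = np.where(valid & ~inside, t - (me[np.clip(j, 0, None)] - 1),
                            np.inf)
        has_right = j + 1 < len(ms)
        right_gap = np.where(has_right & ~inside,
                             ms[np.clip(j + 1, 0, len(ms) - 1)] - t, np.inf)
        dist = np.minimum(dist, np.minimum(left_gap, right_gap))
        out.loc[grp["gene_id"].to_numpy()] = dist
    return out


def window_overlap_ratio(tss: pd.DataFrame, peaks: pd.DataFrame,
                         window: int = 30_000):
    """Fraction of TSSs with a peak within ``window`` bp.

    Returns ``(ratio, flags)`` where flags is a gene_id-indexed boolean
    Series. An empty TSS set is an error; an empty peak set gives ratio 0.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    if len(tss) == 0:
        raise ValueError("empty TSS set")
    if len(peaks) == 0:
        flags = pd.Series(False, index=pd.Index(tss["gene_id"], name="gene_id"))
        return 0.0, flags
    dist = distance_to_nearest_peak(tss, peaks)
    flags = dist <= window
    flags.name = "within_window"
    return float(flags.mean()), flags


def shuffle_tss(tss: pd.DataFrame, chrom_sizes: dict, seed: int = 0, *,
                keep_chromosome: bool = False) -> pd.DataFrame:
    """Uniformly re-place TSSs over the genome (shuffle null).

    Default: each TSS lands on a chromosome drawn with probability
    proportional to its length, position uniform. With ``keep_chromosome``
    the TSS stays on its own chromosome. Cardinality and gene ids are
    preserved; deterministic per seed.
    """
    _require_columns(tss, ("gene_id", "chrom", "tss"), "TSS")
    unknown = set(tss["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"TSS on chromosomes without sizes: {sorted(unknown)}")
    rng = np.random.default_rng(int(seed) % (2**31))
    n = len(tss)
    if keep_chromosome:
        chroms = tss["chrom"].to_numpy()
    else:
        names = list(chrom_sizes)
        sizes = np.array([chrom_sizes[c] for c in names], dtype=float)
        chroms = np.array(names, dtype=object)[
            rng.choice(len(names), size=n, p=sizes / sizes.sum())]
    lengths = np.array([chrom_sizes[c] for c in chroms])
    pos = rng.integers(0, lengths)
    return pd.DataFrame({"gene_id": tss["gene_id"].to_numpy(),
                         "chrom": chroms, "tss": pos})


def window_coverage_fraction(peaks: pd.DataFrame, window: int,
                             chrom_sizes: dict) -> float:
    """Genome fraction within ``window`` bp of any peak.

    The analytic expectation of :func:`window_overlap_ratio` for uniformly
    shuffled TSSs: union coverage of peaks extended by the window on each
    side (clipped to chromosome bounds) divided by total genome length.
    """
    total = float(sum(chrom_sizes.values()))
    covered = 0.0
    for chrom, grp in peaks.groupby("chrom", sort=False):
        size = chrom_sizes[chrom]
        s = np.clip(grp["start"].to_numpy() - window, 0, size)
        e = np.clip(grp["end"].to_numpy() + window, 0, size)
        ms, me = merge_intervals(s, e)
        covered += float((me - ms).sum())
    return covered / total
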