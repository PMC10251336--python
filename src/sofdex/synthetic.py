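"""Synthetic data with known ground truth for every downstream stage.

The generator emulates the statistical structure of a glucocorticoid-receptor
(GR) nascent-RNA time course across three genotypes — wild-type GR, a
separation-of-function (SoF) RNA-binding mutant, and a DNA-affinity-matched
control (Ctrl) mutant — treated with dexamethasone for 0–3 h:

* negative-binomial gene counts (Var = mu + alpha*mu^2) over a genotype x
  time x replicate design with non-trivial library-size factors;
* planted gene classes: direct dex-activated genes, a SoF-amplified subset
  (``sof_dexdep``), a SoF-attenuated subset (``sof_3h_rep``), dex-independent
  constitutively SoF-upregulated genes placed as contiguous runs on a few
  designated chromosomes (``sof_dexind``), and constitutively repressed genes
  (``sof_const_rep``);
* ChIP peaks preferentially placed within a window of direct-target TSSs;
* Cq tables for relative-expression quantification and two-channel cell
  images with elliptical nuclei for the imaging module.

Everything is deterministic given the seed; independent numpy Generator
streams are derived per output so stages can be regenerated in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel, TruthLabels, sort_genomic

GENOTYPES = ("wt", "SoF", "Ctrl")
TIMES = (0, 1, 2, 3)


@dataclass
class SimulationParams:
    """Parameters of the count/genome simulation.

    The defaults define the reference study conditions used throughout the
    test suite: 2,000 genes on 8 x 50 Mb chromosomes, 3 genotypes x 4 times
    x 3 replicates, dispersion 0.05, a 0->1 dex-response ramp over 1-3 h with
    per-gene maxima ~ U(1, 3) log2 units, SoF amplification 2.0, and 60
    clustered dex-independent genes split across chr3/chr7/chr8.
    """

    n_genes: int = 2000
    n_chromosomes: int = 8
    chromosome_length: int = 50_000_000
    min_gene_spacing: int = 5_000
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 2.0
    dispersion: float = 0.05
    n_replicates: int = 3
    # planted class sizes
    n_direct_dex: int = 150
    n_sof_dexdep: int = 50
    n_sof_3h_rep: int = 30
    n_sof_dexind: int = 60
    n_sof_const_rep: int = 60
    # effect sizes (log2 scale)
    dex_profile: tuple = (0.0, 0.5, 0.75, 1.0)   # response ramp at t = 0..3 h
    dex_max_log2fc_range: tuple = (1.5, 3.0)     # per-gene max response
    sof_amplification: float = 2.5               # x on dex response in SoF, sof_dexdep
    sof_3h_attenuation: float = 0.25             # x on dex response in SoF, sof_3h_rep
    sof_dexind_log2fc: float = 1.5
    sof_const_rep_log2fc: float = -1.5
    # spatial clustering of sof_dexind genes
    cluster_fraction: float = 1.0
    cluster_chromosomes: tuple = ("chr3", "chr7", "chr8")
    # library sizes: factors 2^U(lo, hi)
    libsize_log2_range: tuple = (-1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_chromosomes < 1:
            raise ValueError("need at least one chromosome")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("replicate count must be >= 2")
        if self.sof_amplification <= 0:
            raise ValueError("amplification factor must be > 0")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if abs(self.dex_profile[0]) > 0:
            raise ValueError("dex response profile must start at 0 (t=0 is untreated)")
        n_planted = (self.n_direct_dex + self.n_sof_dexdep + self.n_sof_3h_rep
                     + self.n_sof_dexind + self.n_sof_const_rep)
        if n_planted > self.n_genes:
            raise ValueError("planted class sizes exceed n_genes")

    @property
    def chrom_names(self) -> list:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # independent deterministic streams per output kind
    return np.random.default_rng([int(params.seed) % (2**31), stream])


def simulate_genome(params: SimulationParams):
    """Place genes on chromosomes and assign ground-truth classes.

    Dex-independent SoF genes are planted as runs of consecutive genes (in
    TSS order) on ``params.cluster_chromosomes``; all other classes are drawn
    uniformly over the remaining genes. Returns ``(GenomeModel, TruthLabels)``.

    Raises
    ------
    ValueError
        If the requested gene count exceeds what the chromosomes can hold at
        the minimum spacing, or if a planted run does not fit on its
        designated chromosome.
    """
    params.validate()
    rng = _rng(params, 0)
    names = params.chrom_names
    sizes = {name: int(params.chromosome_length) for name in names}

    # distribute genes across chromosomes proportionally to length (equal here)
    counts = np.full(params.n_chromosomes, params.n_genes // params.n_chromosomes)
    counts[: params.n_genes % params.n_chromosomes] += 1

    spacing = int(params.min_gene_spacing)
    records = []
    for name, n_chrom in zip(names, counts):
        slots_available = sizes[name] // spacing
        if n_chrom > slots_available:
            raise ValueError(
                f"{n_chrom} genes do not fit on {name} "
                f"({sizes[name]} bp at {spacing} bp spacing)")
        if n_chrom == 0:
            continue
        slots = np.sort(rng.choice(slots_available, size=n_chrom, replace=False))
        tss = slots * spacing + rng.integers(0, spacing, size=n_chrom)
        for t in tss:
            records.append((name, int(t)))

    genes = pd.DataFrame(records, columns=["chrom", "tss"])
    genes.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(genes))])
    genes["strand"] = "+"
    genome = GenomeModel(chrom_sizes=sizes, genes=genes)

    labels = np.array(["background"] * len(genes), dtype=object)
    cluster_id = np.full(len(genes), -1)

    # planted contiguous runs of sof_dexind genes
    n_clustered = int(round(params.cluster_fraction * params.n_sof_dexind))
    cluster_chroms = [c for c in params.cluster_chromosomes if c in sizes]
    if n_clustered > 0 and not cluster_chroms:
        raise ValueError("no cluster chromosome exists in this genome")
    if n_clustered > 0:
        run_sizes = np.full(len(cluster_chroms), n_clustered // len(cluster_chroms))
        run_sizes[: n_clustered % len(cluster_chroms)] += 1
        for run_idx, (chrom, run_len) in enumerate(zip(cluster_chroms, run_sizes)):
            if run_len == 0:
                continue
            idx = np.flatnonzero((genes["chrom"] == chrom).to_numpy())
            if run_len > len(idx):
                raise ValueError(
                    f"planted run of {run_len} genes exceeds the "
                    f"{len(idx)} genes on {chrom}")
            start = rng.integers(0, len(idx) - run_len + 1)
            sel = idx[start : start + run_len]
            labels[sel] = "sof_dexind"
            cluster_id[sel] = run_idx

    # everything else drawn uniformly over unassigned genes
    pool = np.flatnonzero(labels == "background")
    wanted = [
        ("direct_dex", params.n_direct_dex),
        ("sof_dexdep", params.n_sof_dexdep),
        ("sof_3h_rep", params.n_sof_3h_rep),
        ("sof_dexind", params.n_sof_dexind - n_clustered),
        ("sof_const_rep", params.n_sof_const_rep),
    ]
    total = sum(n for _, n in wanted)
    if total > len(pool):
        raise ValueError("planted class sizes exceed available background genes")
    if total > 0:
        drawn = rng.choice(pool, size=total, replace=False)
        offset = 0
        for label, n in wanted:
            labels[drawn[offset : offset + n]] = label
            offset += n

    truth = TruthLabels(labels=pd.DataFrame({
        "gene_id": genes["gene_id"],
        "label": labels,
        "cluster_id": cluster_id,
    }))
    return genome, truth


def simulate_chip_peaks(genome: GenomeModel, truth: TruthLabels, *,
                        p_near: float = 0.8, window: int = 30_000,
                        n_background: int = 500, peak_width: int = 400,
                        seed: int = 0) -> pd.DataFrame:
    """ChIP peaks preferentially near direct-target TSSs.

    Each ``direct_dex``/``sof_dexdep`` gene receives, with probability
    ``p_near``, one peak whose centre is uniform within ``window`` bp of its
    TSS; ``n_background`` additional peaks are placed uniformly over the
    genome (chromosomes weighted by length). Intervals are clipped to
    chromosome bounds and returned sorted in genome order.
    """
    if not 0.0 <= p_near <= 1.0:
        raise ValueError("p_near must lie in [0, 1]")
    if window <= 0:
        raise ValueError("window must be > 0")
    rng = np.random.default_rng([int(seed) % (2**31), 10])
    half = max(1, peak_width // 2)

    cls = truth.class_of()
    targets = genome.genes[genome.genes["gene_id"].map(cls).isin(
        ["direct_dex", "sof_dexdep"])]
    rows = []
    for _, g in targets.iterrows():
        if rng.random() >= p_near:
            continue
        size = genome.chrom_sizes[g["chrom"]]
        center = int(g["tss"]) + int(rng.integers(-window, window + 1))
        center = int(np.clip(center, half, size - half))
        rows.append((g["chrom"], center - half, center + half))

    sizes = np.array([genome.chrom_sizes[c] for c in genome.chrom_names], dtype=float)
    probs = sizes / sizes.sum()
    for _ in range(int(n_background)):
        ci = rng.choice(len(sizes), p=probs)
        chrom = genome.chrom_names[ci]
        start = int(rng.integers(0, genome.chrom_sizes[chrom] - 2 * half))
        rows.append((chrom, start, start + 2 * half))

    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if len(peaks) == 0:
        return peaks
    peaks = sort_genomic(peaks, genome.chrom_names)
    peaks["name"] = [f"peak{i:05d}" for i in range(len(peaks))]
    return peaks


def _log2fc_matrix(truth: TruthLabels, params: SimulationParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-gene log2 fold change vs (wt, t=0), shape (genes, genotypes, times)."""
    n = len(truth.labels)
    labels = truth.labels["label"].to_numpy()
    profile = np.asarray(params.dex_profile, dtype=float)
    L = np.zeros((n, len(GENOTYPES), len(TIMES)))

    lo, hi = params.dex_max_log2fc_range
    maxfc = rng.uniform(lo, hi, size=n)   # drawn for every gene, used where responsive

    for gi, geno in enumerate(GENOTYPES):
        for cls, mult in (("direct_dex", 1.0),
                          ("sof_dexdep", params.sof_amplification),
                          ("sof_3h_rep", params.sof_3h_attenuation)):
            sel = labels == cls
            factor = mult if geno == "SoF" else 1.0
            L[sel, gi, :] = np.outer(maxfc[sel] * factor, profile)
    sof = GENOTYPES.index("SoF")
    L[labels == "sof_dexind", sof, :] = params.sof_dexind_log2fc
    L[labels == "sof_const_rep", sof, :] = params.sof_const_rep_log2fc
    return L


def simulate_counts(genome: GenomeModel, truth: TruthLabels,
                    params: SimulationParams):
    """NB count matrix over the genotype x time x replicate design.

    Counts are NB with mean ``sizefactor * baseline * 2^L(gene, genotype, t)``
    and Var = mu + alpha*mu^2; t=0 samples carry the ethanol vehicle label and
    no dex response. Returns ``(counts DataFrame genes x samples, design)``.
    """
    params.validate()
    if len(genome.genes) != len(truth.labels):
        raise ValueError("genome and truth tables disagree in length")
    rng = _rng(params, 1)
    n = genome.n_genes

    design_rows = []
    for geno in GENOTYPES:
        for t in TIMES:
            for r in range(1, params.n_replicates + 1):
                design_rows.append({
                    "sample_id": f"{geno}_t{t}_r{r}",
                    "genotype": geno,
                    "treatment": "ethanol" if t == 0 else "dex",
                    "time": t,
                    "replicate": r,
                })
    design = pd.DataFrame(design_rows)

    baseline = 2.0 ** rng.normal(params.baseline_log2_mean,
                                 params.baseline_log2_sd, size=n)
    lo, hi = params.libsize_log2_range
    size_factors = 2.0 ** rng.uniform(lo, hi, size=len(design))
    L = _log2fc_matrix(truth, params, rng)

    geno_idx = design["genotype"].map({g: i for i, g in enumerate(GENOTYPES)}).to_numpy()
    time_idx = design["time"].map({t: i for i, t in enumerate(TIMES)}).to_numpy()
    mu = (size_factors[None, :] * baseline[:, None]
          * 2.0 ** L[:, geno_idx, time_idx])

    if params.dispersion > 0:
        r_nb = 1.0 / params.dispersion
        p_nb = r_nb / (r_nb + mu)
        counts = rng.negative_binomial(r_nb, p_nb)
    else:
        counts = rng.poisson(mu)

    counts = pd.DataFrame(counts.astype(np.int64),
                          index=pd.Index(genome.genes["gene_id"], name="gene_id"),
                          columns=design["sample_id"].tolist())
    return counts, design


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_cq_table(fold_changes, *, control_gene: str = "RPLP0",
                      conditions=("ethanol", "dex_3h"), n_replicates: int = 3,
                      base_cq: float = 20.0, noise_sd: float = 0.15,
                      seed: int = 0) -> pd.DataFrame:
    """Cq table with known fold changes between two conditions.

    ``fold_changes`` maps gene -> expression in ``conditions[1]`` relative to
    ``conditions[0]``. Cq = base + gene offset − log2(expression) + Gaussian
    noise; the control gene is included automatically with fold 1, so with
    ``noise_sd=0`` the ΔΔCq round trip returns each fold exactly.
    """
    if len(conditions) != 2:
        raise ValueError("exactly two conditions expected")
    rng = np.random.default_rng([int(seed) % (2**31), 20])
    genes = dict(fold_changes)
    genes.setdefault(control_gene, 1.0)
    offsets = {g: (0.0 if g == control_gene else rng.uniform(0.0, 5.0))
               for g in genes}
    rows = []
    for ci, cond in enumerate(conditions):
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            for g, fold in genes.items():
                expr = fold if (ci == 1 and g != control_gene) else 1.0
                cq = base_cq + offsets[g] - np.log2(expr)
                if noise_sd > 0:
                    cq += rng.normal(0.0, noise_sd)
                rows.append({"sample_id": sample, "condition": cond,
                             "gene": g, "cq": cq})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------

@dataclass
class SyntheticImage:
    """Two-channel synthetic field of cells plus ground truth."""

    hoechst: np.ndarray          # nuclear-stain channel
    signal: np.ndarray           # GR-signal channel
    nucleus_labels: np.ndarray   # true labeled nuclear mask
    truth: pd.DataFrame          # per cell: planted intensities and fraction


def simulate_cell_image(n_cells: int = 12, shape=(512, 512), *,
                        nuclear_fractions=None, total_signal: float = 200.0,
                        nucleus_axes_range=(10, 18), cell_scale: float = 1.8,
                        stain_intensity: float = 220.0, background: float = 8.0,
                        noise_sd: float = 2.0, seed: int = 0) -> SyntheticImage:
    """Synthetic field of elliptical cells with known nuclear fractions.

    Each cell is an ellipse (nucleus) inside a concentric ellipse scaled by
    ``cell_scale`` (cytoplasm). The signal channel carries per-cell nuclear
    intensity ``total_signal * f`` and cytoplasmic intensity
    ``total_signal * (1 - f)`` so the planted nuclear fraction is ``f``.
    Cells are placed with enough separation that 4-px cytoplasmic rings do
    not contest pixels. Deterministic per seed.
    """
    rng = np.random.default_rng([int(seed) % (2**31), 30])
    h, w = shape
    if nuclear_fractions is None:
        fractions = rng.uniform(0.3, 0.9, size=n_cells)
    else:
        fractions = np.asarray(nuclear_fractions, dtype=float)
        n_cells = len(fractions)

    yy, xx = np.mgrid[0:h, 0:w]
    hoechst = np.full(shape, background, dtype=float)
    signal = np.full(shape, background, dtype=float)
    nucleus_labels = np.zeros(shape, dtype=np.int32)

    a_lo, a_hi = nucleus_axes_range
    margin = int(np.ceil(a_hi * cell_scale)) + 6
    min_sep = 2 * a_hi * cell_scale + 12   # rings never touch

    centers = []
    attempts = 0
    while len(centers) < n_cells and attempts < 20000:
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep**2 for y, x in centers):
            centers.append((cy, cx))
    if len(centers) < n_cells:
        raise ValueError(f"could not place {n_cells} non-touching cells "
                         f"in a {shape} image")

    rows = []
    for label, ((cy, cx), f) in enumerate(zip(centers, fractions), start=1):
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(a_lo, a_hi)
        theta = rng.uniform(0, np.pi)
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        r2 = (u / a) ** 2 + (v / b) ** 2
        nucleus = r2 <= 1.0
        cyto = (r2 <= cell_scale**2) & ~nucleus

        nuc_int = total_signal * f
        cyt_int = total_signal * (1.0 - f)
        hoechst[nucleus] += stain_intensity
        signal[nucleus] += nuc_int
        signal[cyto] += cyt_int
        nucleus_labels[nucleus] = label
        rows.append({"cell": label, "nuclear_intensity": nuc_int,
                     "cytoplasm_intensity": cyt_int,
                     "nuclear_fraction": f if (nuc_int + cyt_int) > 0 else np.nan})

    if noise_sd > 0:
        hoechst = np.clip(hoechst + rng.normal(0, noise_sd, shape), 0, None)
        signal = np.clip(signal + rng.normal(0, noise_sd, shape), 0, None)

    return SyntheticImage(hoechst=hoechst, signal=signal,
                          nucleus_labels=nucleus_labels,
                          truth=pd.DataFrame(rows))
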