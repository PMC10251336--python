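"""Generator invariants: determinism, placement, count marginals, closures."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from sofdex.cooccurrence import window_overlap_ratio
from sofdex.synthetic import (SimulationParams, simulate_cell_image,
                              simulate_chip_peaks, simulate_counts,
                              simulate_cq_table, simulate_genome)


def _runs_of(mask: np.ndarray):
    """Lengths of consecutive-True runs."""
    lengths, run = [], 0
    for v in mask:
        if v:
            run += 1
        elif run:
            lengths.append(run)
            run = 0
    if run:
        lengths.append(run)
    return lengths


class TestSimulateGenome:
    def test_deterministic_given_seed(self, default_params):
        g1, t1 = simulate_genome(default_params)
        g2, t2 = simulate_genome(default_params)
        pd.testing.assert_frame_equal(g1.genes, g2.genes)
        pd.testing.assert_frame_equal(t1.labels, t2.labels)

    def test_tss_within_bounds_and_ids_unique(self, default_sim):
        genome, truth, _, _ = default_sim
        sizes = genome.genes["chrom"].map(genome.chrom_sizes)
        assert (genome.genes["tss"] >= 0).all()
        assert (genome.genes["tss"] < sizes).all()
        assert genome.genes["gene_id"].is_unique

    def test_clustered_genes_are_consecutive_runs(self, default_params):
        genome, truth = simulate_genome(default_params)
        merged = genome.genes.merge(truth.labels, on="gene_id")
        for chrom in default_params.cluster_chromosomes:
            sub = merged[merged["chrom"] == chrom]
            mask = (sub["label"] == "sof_dexind").to_numpy()
            clustered = sub.loc[mask, "cluster_id"] >= 0
            on_chrom = mask & (sub["cluster_id"] >= 0).to_numpy()
            runs = _runs_of(on_chrom)
            assert len(runs) == 1  # one contiguous planted run per chromosome

    def test_cluster_fraction_zero_matches_uniform_run_lengths(self):
        """Without clustering, the longest sof_dexind run is typical of
        uniform placement (Monte-Carlo null on the max run length)."""
        params = dataclasses.replace(SimulationParams(), cluster_fraction=0.0,
                                     seed=7)
        genome, truth = simulate_genome(params)
        merged = genome.genes.merge(truth.labels, on="gene_id")
        observed = max(max(_runs_of((grp["label"] == "sof_dexind").to_numpy()),
                           default=0)
                       for _, grp in merged.groupby("chrom"))
        # null distribution of the max run for 60 marks in 2000 positions
        rng = np.random.default_rng(0)
        null = []
        chrom_sizes = merged.groupby("chrom").size().to_numpy()
        for _ in range(300):
            marks = np.zeros(params.n_genes, dtype=bool)
            marks[rng.choice(params.n_genes, params.n_sof_dexind,
                             replace=False)] = True
            best, start = 0, 0
            for sz in chrom_sizes:
                best = max(best, max(_runs_of(marks[start:start + sz]),
                                     default=0))
                start += sz
            null.append(best)
        assert observed <= np.quantile(null, 0.99)

    def test_zero_genes_gives_valid_empty_model(self):
        params = dataclasses.replace(
            SimulationParams(), n_genes=0, n_direct_dex=0, n_sof_dexdep=0,
            n_sof_3h_rep=0, n_sof_dexind=0, n_sof_const_rep=0)
        genome, truth = simulate_genome(params)
        assert genome.n_genes == 0
        assert len(truth.labels) == 0

    def test_overfull_chromosomes_rejected(self):
        params = dataclasses.replace(SimulationParams(), n_genes=10_000,
                                     chromosome_length=1_000_000,
                                     min_gene_spacing=5_000)
        with pytest.raises(ValueError, match="fit"):
            simulate_genome(params)


class TestSimulateChipPeaks:
    def test_p_near_one_no_background_covers_every_target(self, default_sim):
        genome, truth, _, _ = default_sim
        peaks = simulate_chip_peaks(genome, truth, p_near=1.0,
                                    n_background=0, seed=3)
        cls = truth.class_of()
        targets = genome.genes[genome.genes["gene_id"].map(cls).isin(
            ["direct_dex", "sof_dexdep"])]
        ratio, _ = window_overlap_ratio(targets[["gene_id", "chrom", "tss"]],
                                        peaks, 30_000)
        assert ratio == 1.0

    def test_p_near_zero_no_background_is_empty(self, default_sim):
        genome, truth, _, _ = default_sim
        peaks = simulate_chip_peaks(genome, truth, p_near=0.0,
                                    n_background=0, seed=3)
        assert len(peaks) == 0

    def test_hit_rate_within_binomial_interval(self, default_sim):
        genome, truth, _, _ = default_sim
        p_near = 0.8
        peaks = simulate_chip_peaks(genome, truth, p_near=p_near,
                                    n_background=0, seed=5)
        cls = truth.class_of()
        n_targets = int(genome.genes["gene_id"].map(cls).isin(
            ["direct_dex", "sof_dexdep"]).sum())
        se = np.sqrt(p_near * (1 - p_near) / n_targets)
        assert abs(len(peaks) / n_targets - p_near) < 4 * se

    def test_sorted_and_in_bounds(self, default_sim):
        genome, truth, _, _ = default_sim
        peaks = simulate_chip_peaks(genome, truth, seed=1)
        for chrom, grp in peaks.groupby("chrom"):
            assert grp["start"].is_monotonic_increasing
            assert (grp["end"] <= genome.chrom_sizes[chrom]).all()
            assert (grp["start"] >= 0).all()

    def test_invalid_window_rejected(self, default_sim):
        genome, truth, _, _ = default_sim
        with pytest.raises(ValueError, match="window"):
            simulate_chip_peaks(genome, truth, window=0)


class TestSimulateCounts:
    def test_deterministic_given_seed(self, default_params, default_sim):
        genome, truth, counts, design = default_sim
        counts2, design2 = simulate_counts(genome, truth, default_params)
        pd.testing.assert_frame_equal(counts, counts2)
        pd.testing.assert_frame_equal(design, design2)

    def test_design_covers_full_grid(self, default_sim):
        _, _, _, design = default_sim
        grid = design.groupby(["genotype", "time"]).size()
        assert (grid == 3).all()
        assert set(design["genotype"]) == {"wt", "SoF", "Ctrl"}
        assert set(design["time"]) == {0, 1, 2, 3}
        assert (design.loc[design["time"] == 0, "treatment"] == "ethanol").all()
        assert (design.loc[design["time"] > 0, "treatment"] == "dex").all()

    def test_poisson_limit_variance_matches_mean(self):
        """alpha -> 0: per-gene sample variance tracks the mean."""
        params = dataclasses.replace(
            SimulationParams(), dispersion=0.0, n_genes=500,
            n_direct_dex=0, n_sof_dexdep=0, n_sof_3h_rep=0, n_sof_dexind=0,
            n_sof_const_rep=0, libsize_log2_range=(0.0, 0.0),
            baseline_log2_mean=7.0, baseline_log2_sd=0.5, n_replicates=12,
            seed=2)
        genome, truth = simulate_genome(params)
        counts, _ = simulate_counts(genome, truth, params)
        x = counts.to_numpy(dtype=float)
        ratio = x.var(axis=1, ddof=1) / x.mean(axis=1)
        assert abs(np.median(ratio) - 1.0) < 0.1

    def test_nb_marginal_dispersion_recovered(self):
        """Per-gene moments match NB(mu, alpha) at the default dispersion."""
        params = dataclasses.replace(
            SimulationParams(), n_genes=2000, n_direct_dex=0, n_sof_dexdep=0,
            n_sof_3h_rep=0, n_sof_dexind=0, n_sof_const_rep=0,
            libsize_log2_range=(0.0, 0.0), n_replicates=12, seed=3)
        genome, truth = simulate_genome(params)
        counts, _ = simulate_counts(genome, truth, params)
        x = counts.to_numpy(dtype=float)
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        alpha_hat = np.median((v - m) / m**2)
        assert 0.5 * params.dispersion < alpha_hat < 2.0 * params.dispersion

    def test_amplification_one_makes_genotypes_exchangeable(self):
        """With amplification 1 the SoF and Ctrl dex responses of the planted
        set come from the same distribution (two-sample test, seed batch)."""
        from scipy import stats
        params = dataclasses.replace(SimulationParams(), sof_amplification=1.0,
                                     seed=4)
        genome, truth = simulate_genome(params)
        counts, design = simulate_counts(genome, truth, params)
        from sofdex import diffexpr
        sf = diffexpr.median_of_ratios(counts)
        disp = diffexpr.estimate_dispersion(counts, design, size_factors=sf)
        fc = {}
        for geno in ("SoF", "Ctrl"):
            res = diffexpr.nb_wald_test(
                counts, design, diffexpr.time_contrast(design, geno, 3),
                size_factors=sf, dispersions=disp)
            dexdep = truth.genes_in_class("sof_dexdep")
            fc[geno] = res.table.loc[dexdep, "log2FoldChange"].to_numpy()
        p = stats.mannwhitneyu(fc["SoF"], fc["Ctrl"]).pvalue
        assert p > 0.01


class TestCqAndImage:
    def test_noise_free_twofold_gives_ddcq_minus_one(self):
        from sofdex.qpcr import delta_cq, delta_delta_cq
        table = simulate_cq_table({"BIRC3": 2.0}, noise_sd=0.0, seed=0)
        dcq = delta_cq(table, "RPLP0")
        ddcq = delta_delta_cq(dcq, "dex_3h", "ethanol")
        assert ddcq["BIRC3"] == pytest.approx(-1.0, abs=1e-12)

    def test_pure_nuclear_signal_has_fraction_one(self):
        img = simulate_cell_image(n_cells=3, nuclear_fractions=[1.0, 1.0, 1.0],
                                  background=0.0, noise_sd=0.0, seed=0)
        assert (img.truth["cytoplasm_intensity"] == 0).all()
        assert (img.truth["nuclear_fraction"] == 1.0).all()

    def test_image_regeneration_identical(self):
        a = simulate_cell_image(n_cells=5, seed=9)
        b = simulate_cell_image(n_cells=5, seed=9)
        np.testing.assert_array_equal(a.hoechst, b.hoechst)
        np.testing.assert_array_equal(a.signal, b.signal)
        np.testing.assert_array_equal(a.nucleus_labels, b.nucleus_labels)

    def test_cq_table_regeneration_identical(self):
        a = simulate_cq_table({"A": 2.0}, seed=5)
        b = simulate_cq_table({"A": 2.0}, seed=5)
        pd.testing.assert_frame_equal(a, b)


def test_invalid_params_rejected():
    for kwargs in ({"dispersion": -0.1}, {"n_replicates": 1},
                   {"sof_amplification": 0.0}, {"cluster_fraction": 1.5}):
        with pytest.raises(ValueError):
            dataclasses.replace(SimulationParams(), **kwargs).validate()
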