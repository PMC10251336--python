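import dataclasses

import pandas as pd
import pytest

from sofdex.synthetic import SimulationParams, simulate_counts, simulate_genome


@pytest.fixture(scope="session")
def default_params() -> SimulationParams:
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def default_sim(default_params):
    """Genome, truth and counts at the default study conditions (seed 1)."""
    genome, truth = simulate_genome(default_params)
    counts, design = simulate_counts(genome, truth, default_params)
    return genome, truth, counts, design


@pytest.fixture(scope="session")
def small_genome_params() -> SimulationParams:
    """200-gene universe with a single planted 10-gene run on chr3."""
    return dataclasses.replace(
        SimulationParams(), n_genes=200, chromosome_length=10_000_000,
        n_direct_dex=0, n_sof_dexdep=0, n_sof_3h_rep=0, n_sof_const_rep=0,
        n_sof_dexind=10, cluster_chromosomes=("chr3",), seed=0)


def make_design(sample_ids, **cols) -> pd.DataFrame:
    """Minimal single-condition design for dispersion/DE unit tests."""
    base = {"sample_id": list(sample_ids), "genotype": "wt",
            "treatment": "ethanol", "time": 0,
            "replicate": list(range(1, len(sample_ids) + 1))}
    base.update(cols)
    return pd.DataFrame(base)
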