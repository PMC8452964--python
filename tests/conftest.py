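"""Shared fixtures: a small simulated genome reused across module tests."""

import numpy as np
import pytest

from pmdscape import density, simulate


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(
        seed=11, chrom_lengths={"chr1": 2_000_000, "chr2": 1_000_000}, n_cell_types=2
    )


@pytest.fixture(scope="session")
def small_genome(small_config):
    rng = np.random.default_rng(small_config.seed)
    return simulate.simulate_genome(small_config, rng)


@pytest.fixture(scope="session")
def small_truth(small_genome, small_config):
    rng = np.random.default_rng(small_config.seed + 1)
    return simulate.plant_pmds(small_genome, small_config, rng)


@pytest.fixture(scope="session")
def small_methylomes(small_genome, small_config, small_truth):
    rng = np.random.default_rng(small_config.seed + 2)
    return simulate.simulate_methylomes(small_genome, small_config, small_truth, rng)


@pytest.fixture(scope="session")
def site_table(small_genome):
    return small_genome.site_table()


def unit_ucg_calls(genome, methylome, config, rng, sites=None):
    """Helper: one technical replicate of uCG unit-level calls."""
    sites = genome.site_table() if sites is None else sites
    reads = simulate.simulate_reads(genome, methylome, config, rng, mode="u")
    cov, _ = density.assign_reads_to_sites(reads, sites, config.max_offset)
    return density.unit_coverage(cov, sites, genome.cg_units) >= 1
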