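import numpy as np
import pytest

import magicpop as mp


@pytest.fixture(scope="session")
def small_map():
    """Three short chromosomes, 30 SNPs — enough for structural tests."""
    return mp.uniform_map(n_snps=30, chromosomes=("1A", "2B", "3D"), length_cm=100.0)


@pytest.fixture(scope="session")
def small_panel(small_map):
    rng = np.random.default_rng(11)
    return mp.simulate_founder_alleles(small_map.snp_ids, rng)


@pytest.fixture(scope="session")
def wheat_map():
    """Full 21-chromosome map at test marker density."""
    return mp.uniform_map(n_snps=420)


@pytest.fixture(scope="session")
def wheat_panel(wheat_map):
    rng = np.random.default_rng(12)
    return mp.simulate_founder_alleles(wheat_map.snp_ids, rng)


@pytest.fixture(scope="session")
def wheat_population(wheat_map, wheat_panel):
    """300 clean-genotyped lines on the 21-chromosome map (shared, read-only)."""
    rng = np.random.default_rng(13)
    config = mp.SimConfig(target_lines=300, missing_rate=0.0, het_error_rate=0.0)
    lines = mp.build_population(wheat_panel, wheat_map, config, rng)
    geno = mp.genotype_lines(lines, wheat_panel, wheat_map, config, rng)
    return lines, geno
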