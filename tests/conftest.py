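import numpy as np
import pandas as pd
import pytest

from allomap.classification import classify_matrix
from allomap.synthetic_data import (
    SimulationConfig,
    default_genome,
    simulate_population,
)


@pytest.fixture(scope="session")
def genome_2hg():
    """2 HGs x 4 subgenomes, 20 evenly spaced loci per 60 cM chromosome."""
    return default_genome(n_hg=2, n_subgenomes=4, loci_per_chrom=20,
                          chrom_length_cm=60.0, fraction_specific=0.7, seed=11)


@pytest.fixture(scope="session")
def pop_clean(genome_2hg):
    cfg = SimulationConfig(n_individuals=164, error_rate=0.0, missing_rate=0.0,
                           seed=21)
    return simulate_population(genome_2hg, cfg)


@pytest.fixture(scope="session")
def pop_noisy(genome_2hg):
    cfg = SimulationConfig(n_individuals=164, error_rate=0.01,
                           missing_rate=0.02, seed=22)
    return simulate_population(genome_2hg, cfg)


@pytest.fixture(scope="session")
def classes_clean(pop_clean):
    matrix, _ = pop_clean
    return classify_matrix(matrix)


@pytest.fixture(scope="session")
def anchors_clean(pop_clean):
    _, truth = pop_clean
    return truth[["ref_chrom", "ref_pos"]]
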