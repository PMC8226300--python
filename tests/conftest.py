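"""Shared fixtures: small synthetic datasets reused across test modules.

Session scope keeps the simulators' cost amortised; every fixture is
seeded so the whole suite is deterministic.
"""

import pytest

from chlamycomp.simulate import (
    AlignmentSpec,
    GenomeSpec,
    simulate_alignment,
    simulate_genome,
    simulate_variants,
)


@pytest.fixture(scope="session")
def sim_small():
    """60-gene genome on 2 × 250 kb contigs."""
    return simulate_genome(GenomeSpec(seed=1, n_genes=60, seq_length=250_000))


@pytest.fixture(scope="session")
def aln_small(sim_small):
    return simulate_alignment(sim_small, AlignmentSpec(seed=2))


@pytest.fixture(scope="session")
def var_small(sim_small):
    table, truth = simulate_variants(sim_small, seed=3)
    return table


@pytest.fixture(scope="session")
def sim_medium():
    """150-gene genome used for the classifier-recovery tests."""
    return simulate_genome(GenomeSpec(seed=5, n_genes=150, seq_length=500_000))


@pytest.fixture(scope="session")
def var_medium(sim_medium):
    table, truth = simulate_variants(sim_medium, seed=7)
    return table
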