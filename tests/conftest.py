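"""Shared fixtures: small truth-tracked genomes generated once per session."""

import pytest

from baculokit.synthetic_data import SimConfig, generate_genome


@pytest.fixture(scope="session")
def small_genome():
    """A 20-kb genome with 10 ORFs, 3 hrs and planted restriction sites."""
    cfg = SimConfig(
        genome_length=20_000,
        n_orfs=10,
        n_hrs=3,
        orf_length_range=(153, 900),
        n_promoter_orfs=4,
        seed=11,
    )
    genome, truth = generate_genome(cfg)
    return genome, truth


@pytest.fixture(scope="session")
def perfect_genome():
    """Same scale but with perfectly conserved repeat units (divergence 0)."""
    cfg = SimConfig(
        genome_length=20_000,
        n_orfs=8,
        n_hrs=3,
        orf_length_range=(153, 600),
        unit_divergence=0.0,
        n_promoter_orfs=3,
        seed=23,
    )
    genome, truth = generate_genome(cfg)
    return genome, truth
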