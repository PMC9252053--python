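"""Shared fixtures: a small locus (6 kb) with scaled-down alleles for
fast unit tests, and the full-geometry locus for tests that need the
published allele sizes."""

import pytest

from petalotype.alleles import apply_allele, junctions
from petalotype.simulate import (
    AlleleSpec,
    SimulationConfig,
    make_alleles,
    make_locus,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        locus_length=6_000,
        gc_fraction=0.4,
        tss_offset=2_500,
        transcript_length=800,
        premirna_offset=200,
        premirna_length=119,
        allele_specs=(
            AlleleSpec("ins1", "insertion", 900, offset=120, source="ltr-flanked", repeat_length=100),
            AlleleSpec("ins2", "insertion", 400, offset=200, source="random"),
            AlleleSpec("del1", "deletion", 1401, start_offset=-300, end_offset=1100),
        ),
        short_read_length=100,
        coverage=25.0,
        long_read_n50=2_500,
        long_read_min_length=400,
        n_snp_samples=120,
        n_snps=40,
        ld_block_length=1_000,
    )


@pytest.fixture(scope="session")
def small_locus(small_config):
    return make_locus(small_config)


@pytest.fixture(scope="session")
def small_alleles(small_config, small_locus):
    return make_alleles(small_locus, small_config)


@pytest.fixture(scope="session")
def small_haplotypes(small_locus, small_alleles):
    haps = {"wt": small_locus.sequence}
    for a in small_alleles:
        haps[a.label], _ = apply_allele(small_locus, a)
    return haps


@pytest.fixture(scope="session")
def small_junction_sets(small_locus, small_alleles):
    return [junctions(small_locus, a, flank=50) for a in small_alleles]


@pytest.fixture(scope="session")
def full_config() -> SimulationConfig:
    """Published geometry on the default 50 kb locus."""
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def full_locus(full_config):
    return make_locus(full_config)


@pytest.fixture(scope="session")
def full_alleles(full_config, full_locus):
    return make_alleles(full_locus, full_config)
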