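"""Shared fixtures: small simulated populations reused across tests."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

import bluebin as bb


@dataclass
class Population:
    genome: bb.Genome
    truth: bb.CrossTruth
    matrix: bb.SnpMatrix
    filtered: bb.SnpMatrix
    tracks: dict
    corrected: dict
    breakpoints: list
    binset: bb.BinSet


def _make_population(n_chromosomes, snp_density, n_progeny, seed) -> Population:
    genome = bb.simulate_genome(
        bb.GenomeConfig(n_chromosomes=n_chromosomes, chrom_length_bp=1_000_000,
                        snp_density=snp_density, seed=seed)
    )
    truth = bb.simulate_cross(genome, n_progeny=n_progeny, seed=seed + 1)
    matrix = bb.observe_genotypes(truth, seed=seed + 2)
    filtered, _, _ = bb.full_filter(matrix)
    tracks, corrected, breakpoints = bb.genotype_population(filtered)
    binset = bb.deduce_bins(filtered, tracks, corrected)
    return Population(genome, truth, matrix, filtered, tracks, corrected,
                      breakpoints, binset)


@pytest.fixture(scope="session")
def pop() -> Population:
    """Two-chromosome, 60-progeny population: fast shared workhorse."""
    return _make_population(n_chromosomes=2, snp_density=1e-3,
                            n_progeny=60, seed=42)


@pytest.fixture(scope="session")
def mapped_pop(pop) -> tuple[Population, bb.GeneticMap]:
    return pop, bb.build_map(pop.binset)
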