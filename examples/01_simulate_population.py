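"""Simulate a pseudo-backcross population with full truth.

Builds a small two-chromosome genome at the study's SNP density, crosses
an interspecific F1 (P1) to an unrelated diploid (P2) for 117 progeny,
and samples noisy low-coverage genotype observations.
"""

import numpy as np

import bluebin as bb

genome = bb.simulate_genome(bb.GenomeConfig(
    n_chromosomes=2, chrom_length_bp=1_000_000, snp_density=4.08e-4, seed=1))
truth = bb.simulate_cross(genome, n_progeny=117, seed=2)
matrix = bb.observe_genotypes(truth, bb.ObservationModel(), seed=3)

print(f"genome: {genome.n_sites} SNPs on {len(genome.scaffolds)} scaffolds "
      f"({genome.sites['marker_type'].value_counts().to_dict()})")
xo = truth.crossover_table()
print(f"cross: {truth.n_progeny} progeny, {len(xo)} crossovers "
      f"(mean {len(xo) / (2 * 2 * truth.n_progeny):.2f} per gamete per chromosome)")
obs_err = (matrix.progeny_calls() != truth.true_genotypes()) \
    & (matrix.progeny_calls() != bb.MISSING)
print(f"observation: {(matrix.calls == bb.MISSING).mean():.2%} missing calls, "
      f"{obs_err.mean():.3%} wrong calls")
# The marker-type mix mirrors an interspecific-F1 x outcross design: most
# sites segregate through P1; wrong calls are what the sliding window absorbs.
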