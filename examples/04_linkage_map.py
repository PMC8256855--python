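"""Linkage-map construction: grouping, ordering, Kosambi distances.

Groups bins at rf <= 0.35 and LOD >= 12, orders each group by greedy
seriation with 2-opt refinement, and prints per-group summaries in the
style of a published map table.
"""

import bluebin as bb
from bluebin.linkage import map_summary

genome = bb.simulate_genome(bb.GenomeConfig(
    n_chromosomes=3, chrom_length_bp=1_000_000, snp_density=1e-3, seed=31))
truth = bb.simulate_cross(genome, n_progeny=117, seed=32)
matrix = bb.observe_genotypes(truth, seed=33)
filtered, _, _ = bb.full_filter(matrix)
tracks, corrected, _ = bb.genotype_population(filtered)
binset = bb.deduce_bins(filtered, tracks, corrected)

gmap = bb.build_map(binset, rf_max=0.35, lod_min=12.0)
summary = gmap.lg_summary()
print(summary.to_string(index=False))
totals = map_summary(summary)
print(f"total: {totals['total_bins']} bins, {totals['total_snps']} SNPs, "
      f"{totals['total_length_cm']} cM in {totals['n_groups']} groups")
print(f"kosambi: rf 0.20 -> {bb.kosambi(0.2):.2f} cM; "
      f"inverse(21.18 cM) -> {bb.kosambi_inverse(21.18):.3f}")
# Each simulated chromosome (100 cM) is recovered as one linkage group;
# the map length approximates the true length minus unsampled chromosome tails.
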