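"""Recompute the published diploid-blueberry map and QTL arithmetic.

The packaged reference tables carry the published per-LG map summary
and the multi-year QTL table; map_summary and qtl_report must
reproduce the printed totals and means exactly.
"""

import bluebin as bb
from bluebin.linkage import map_summary

totals = map_summary(bb.load_reference_map_summary())
print(f"map: {totals['total_snps']} SNPs in {totals['total_bins']} bins, "
      f"{totals['total_length_cm']} cM across {totals['n_groups']} LGs "
      f"(mean {totals['mean_lg_length_cm']} cM, "
      f"{totals['mean_snps_per_lg']} SNPs/LG, "
      f"{totals['total_gaps_gt10']} gaps > 10 cM)")

supported, single = bb.qtl_report(bb.load_reference_qtl_summary())
for _, row in supported.iterrows():
    print(f"{row['trait']:>9} LG{row['lg']:>2} ({row['n_years']} years): "
          f"mean peak LOD {row['mean_peak_lod']:.1f}, "
          f"mean R2 {100 * row['mean_r2']:.1f}%, "
          f"mean R2/H2 {100 * row['mean_r2_over_h2']:.1f}%")
# Multi-year support is the conventional criterion for calling a QTL real:
# co-locating intervals on the same linkage group in at least two years.
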