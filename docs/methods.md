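# Methods

## Study design being modelled

The package targets the analysis of a diploid pseudo-backcross:
an interspecific F1 (called P1 throughout) crossed to an unrelated
diploid (P2), genotyped at biallelic SNPs on draft-assembly scaffolds.
Each retained SNP is heterozygous in at least one parent and falls
into one of three marker types — P1HET (AB x AA), P2HET (AA x AB) or
BOTHHET (AB x AB).  Testcross-type sites segregate 1:1 among progeny,
BOTHHET sites 1:2:1.  Every downstream stage treats the two parental
meioses of an individual as separate "transmission tracks".

## Variant filtering

Filter chain, in fixed order: biallelic → site QUAL ≥ 30 (per-call
GQ < 30 first set MISSING) → mean depth in [3, 750] → both parents
called with ≥ 1 heterozygous → progeny missingness ≤ 50% →
chi-square segregation test at α = 0.05 (critical values computed
from the χ² quantile function; they round to 3.84 at df = 1 and 5.99
at df = 2).  The order affects only the attribution of removals in
the report; the surviving set is order-independent and the chain is
idempotent.  A joint site/genotype quality threshold is deliberately
read in the strictest consistent way (both QUAL and GQ at 30).
Mendelian-impossible calls (e.g. BB at an AB x AA site) are treated as
genotyping errors: set MISSING, tallied per site, excluded from the
segregation counts — they are precisely what the sliding window is
designed to absorb, so they do not fail the site.  The 50%-missing
rule counts progeny only; parents are already required non-missing.

Note that per-site segregation tests are strongly correlated along a
chromosome (adjacent sites share the same meioses), so the ~5%
null-removal rate holds marginally but realises in clumps: a region
where the sampled population drifts from 1:1 is removed wholesale.

## Parent-dependent sliding window

Painting. Progeny calls are decomposed per marker type: at a
testcross site the heterozygous parent's transmitted allele is the
progeny genotype minus the homozygous parent's contribution (invalid
results are Mendelian errors → MISSING); at BOTHHET sites AA → (A,A)
and BB → (B,B) on both tracks while AB is phase-ambiguous → MISSING.

Window rule. One window per start index, stride one SNP, default 15
informative SNPs (windows at a scaffold tail are evaluated truncated,
with no padding).  The window state is the *dominant* state read as a
strict majority of non-missing entries with minimum support
⌈width/3⌉; ties or thin support give MISSING.  Each site is then
assigned the majority state over the windows covering it, and runs of
equal site states form genotype blocks (interior MISSING runs merge
into their flanks).  A window-size ladder (5–19) can be scored on the
parents' own call tracks — the fraction of windows whose dominant
call is AB where the parent is known heterozygous — and the smallest
size within tolerance of the maximum chosen; the pipeline default
pins 15.

Breakpoints and correction. Adjacent blocks of different state imply
a crossover.  Because the smoothed boundary only localises it to a
few sites, the cut is refined against the *raw* states: the split
minimising raw-state mismatches within 15 sites of the smoothed
boundary (ties → middle cut).  The reported breakpoint interval runs
from the last raw site supporting the left state to the first
supporting the right state, with the midpoint as the assigned
position.  Tracks are then corrected to block consensus through the
refined cut, so every site between the first and last block carries a
definite state.  This correction is what lets adjacent-bin
recombination fractions see each crossover exactly once; without it,
crossovers hide inside missing gaps and the map collapses.

Bins. A marker bin is a maximal run of sites whose corrected
population profile (all individuals × both tracks) is constant; each
corrected run extends to the site before the next informative site of
its track, so bins tile each scaffold completely and bin SNP counts
sum to the filtered site count.

## Linkage map

Two-point estimation counts recombinants directly on the phased bin
profiles, per parent track, with the linkage phase chosen per track
by maximum likelihood (coupling vs repulsion = whichever mismatch
count is smaller); the two tracks' meioses pool into
r̂ = R/N and LOD = R log10 r̂ + (N−R) log10(1−r̂) + N log10 2.  Pairs
informative through disjoint parents, or with fewer than 20 shared
meioses, are unusable (r = 0.5, LOD = 0).  A separate
maximum-likelihood estimator for *unphased* 1:2:1 genotype pairs
(`rf_from_unphased_genotypes`) enumerates the four phase
configurations and maximises the 3x3 joint-genotype likelihood by
bounded 1-D search; in this pipeline the window/block stage resolves
phase before bins form, so it serves as an independent cross-check
rather than a pipeline step.

Grouping takes connected components of the graph with edges where
r ≤ 0.35 AND LOD ≥ 12; singletons are reported unplaced, groups are
numbered by descending SNP content.  Ordering is greedy seriation
seeded at the strongest-LOD pair, extending the chain at the end with
the smallest rf, then 2-opt segment reversals until the sum of
adjacent recombination fractions stops decreasing (deterministic
tie-breaks on rf, LOD, then bin index).  Orientation follows the
scaffold coordinate of the first bin.  Positions are cumulative
Kosambi transforms of adjacent-pair rf (clamped at 0.49); no
multipoint HMM is used, on the grounds that corrected bins are
high-confidence markers and the published distances rest on the same
Kosambi choice.

## QTL scans

Haley–Knott regression interval mapping.  At each grid position
(0.5 cM default step per linkage group) the expected
B-transmission indicator of each track is computed from the nearest
non-missing flanking bins by the standard no-interference conditional
formula with Kosambi-inverse recombination fractions, normalised over
the two states (exact 0/1 at a genotyped bin; single-flank
conditioning at group ends; 0.5 with no information).  The phenotype
is regressed on the two indicators; LOD = (n/2) log10(RSS0/RSS1).
The scan engine precomputes an orthonormal basis of every centred
design so that thresholds and many-trait scans reduce to one matrix
product — 200 traits x 200 permutations run in seconds.

Thresholds: phenotype rows are permuted jointly against the genotype
matrix (preserving genotype LD), and the cutoff is the empirical
(1−α) quantile (upper order statistic) of the per-permutation
genome-wide maximum LOD; 1,000 permutations at α = 0.05 by default.
Peaks are maxima of contiguous super-threshold segments; support
intervals walk from the peak to the LOD−1 drop on each side and
extend outward to the nearest bin boundaries, with truncation flags
at group ends.  R² = 1 − RSS1/RSS0 at the peak; R²/H² divides by the
trait's broad-sense heritability and is capped at 1.0 (flagged) when
the scan — typically run on clone means, which shrink the error
variance — explains more than the per-plot heritable variance.
QTLs of one trait whose bin intervals overlap on the same linkage
group in ≥ 2 years are reported "supported", with per-QTL means of
peak LOD, R² and R²/H² across the supporting years (the ratio mean is
the mean of per-year ratios).  An optional composite mode
forward-selects bin cofactors (partial F at p < 0.01, bounded count)
and excludes cofactors within a 10 cM window of the test position;
plain interval mapping is the default because it is fully specified.

## Synthetic data

The simulator emulates the study conditions: 12 chromosomes, 4.08
SNPs per 10 kbp, marker-type mix 90:50:20 (P1HET:P2HET:BOTHHET,
reflecting the interspecific F1's excess heterozygosity), Poisson
scaffold breaks (draft-assembly emulation), 117 progeny, uniform
cM↔bp within a chromosome, and crossovers as a Poisson process
(mean L/100 per gamete; an optional gamma-renewal mode adds
interference).  Phase convention: haplotype 0 of each parent carries
the reference allele at all of that parent's heterozygous sites
(coupling throughout) — transmitted-allele tracks are then locally
constant within haplotype segments, which is the property the window
smoother requires.  Real data would need a parental phasing step
first; the simulator does not model phase switching, and that is the
main respect in which passing tests understate the difficulty of real
input.

Observation model: per-call depth is gamma-Poisson with mean 20
(dispersion 6; parents 3x deeper, mirroring their larger share of
sequencing), each read misreports the allele with probability 0.0013,
depth < 3 is MISSING, and a call is heterozygous iff the minor allele
has ≥ 2 reads.  Genotype qualities are Phred-scaled likelihood ratios
under the same binomial model, which makes low-depth homozygous calls
fail GQ 30 more often than heterozygous ones — a realistic asymmetry
that slightly biases per-site genotype ratios and exercises the
segregation filter.  Progeny depth is not stated by the study design
being emulated; 20x was chosen once as typical for targeted capture
and not revisited.  Traits are additive over per-gamete QTL effects
with i.i.d. normal noise scaled so that Vg/(Vg+Ve) matches the target
per-plot H² given the realised genetic variance; clone replicates
(default 3) make H² estimable by one-way ANOVA.  Not modelled:
read-level artifacts, alignment error, segregation distortion with a
biological cause, genotyping-error correlation between sites.

## Problem sizes and numerical choices

The validation battery runs the pipeline at reduced scale chosen to
keep the statistics meaningful: linkage-group recovery on 12
chromosomes x ~2,000 sites x 117 progeny; null-trait type-I error on
a 3-chromosome map with 200 permutations x 200 traits; single-QTL
(h² ≈ 0.3) localisation over 50 two-chromosome replicates.  Matrix
products use float32 for the all-pairs recombination counts (counts
≤ 234 are exactly representable); RSS ratios are floored at 1e-12 of
RSS0 before taking logarithms; degenerate scan designs (constant
indicator columns) are handled by rank-revealing SVD with zero-padded
bases.  All stage seeds derive from one master seed via seed
sequences, and rerunning the pipeline with the same configuration
reproduces byte-identical artifacts (the manifest records parameters
and input checksums, no timestamps).

## Known limitations

- No parental phasing: the pipeline assumes phased transmitted-allele
  tracks, valid for the simulator's coupling convention but requiring
  an upstream phasing step on real outcross data.
- Distances are adjacent-pair two-point estimates; no multipoint
  likelihood, so local ordering errors inflate lengths slightly and
  chromosome tails beyond the first/last bin are unsampled.
- The segregation filter removes drifted regions wholesale (correlated
  tests), which can thin coverage locally.
- Interval mapping fits one QTL at a time; linked QTL absorb into one
  peak unless the composite mode separates them.
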