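"""Synthetic pseudo-backcross population with full truth.

Emulates the study design of a diploid blueberry mapping cross: an
interspecific F1 (``P1``) crossed to an unrelated diploid (``P2``),
giving ~117 progeny scored at biallelic SNPs on fragmented draft-genome
scaffolds.  Each SNP segregates in one of three marker types (P1
heterozygous, P2 heterozygous, or both), and observed genotypes carry
low-coverage sequencing noise (depth sampling, per-read base error,
missing calls).

The simulator records complete truth — founder haplotype segments,
crossover positions, QTL effects — so every downstream stage
(filtering, window genotyping, mapping, QTL scans) can be scored
against it.

Phase convention: at every site where a parent is heterozygous, its
haplotype 0 carries the reference (A) allele and haplotype 1 the
alternate (B) allele.  Transmitted-allele tracks are therefore locally
constant within a haplotype segment, which is what the sliding-window
smoother assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AA, AB, BB, MISSING, BOTHHET, P1HET, P2HET, SnpMatrix

DEFAULT_N_PROGENY = 117
# expected marker-type mix (P1HET : P2HET : BOTHHET), scaled from the
# ~90k : 50k : 20k site counts typical of an interspecific F1 x outcross
DEFAULT_TYPE_WEIGHTS = (90.0, 50.0, 20.0)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class GenomeConfig:
    """Genome layout for the simulated cross.

    ``snp_density`` is SNPs per basepair; the default corresponds to
    4.08 SNPs per 10 kbp.  ``scaffold_break_rate`` is the expected
    number of assembly breaks per chromosome (a draft-assembly
    emulation); breaks fall between SNPs, never on one.
    """

    n_chromosomes: int = 12
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 1_000_000
    snp_density: float = 4.08e-4
    scaffold_break_rate: float = 2.0
    marker_type_weights: tuple[float, float, float] = DEFAULT_TYPE_WEIGHTS
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        if self.chrom_length_cm <= 0 or self.chrom_length_bp <= 0:
            raise ConfigurationError("chromosome lengths must be positive")
        if self.snp_density <= 0:
            raise ConfigurationError("snp_density must be positive")
        if self.scaffold_break_rate < 0:
            raise ConfigurationError("scaffold_break_rate must be >= 0")


@dataclass
class Genome:
    """Simulated genome truth: scaffolds and SNP sites with marker types."""

    config: GenomeConfig
    sites: pd.DataFrame  # chrom, chrom_bp, cm, scaffold, pos, marker_type, ref, alt
    scaffolds: pd.DataFrame  # chrom, scaffold, start_bp, end_bp

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def bp_per_cm(self) -> float:
        return self.config.chrom_length_bp / self.config.chrom_length_cm

    def cm_of_bp(self, chrom_bp) -> np.ndarray:
        return np.asarray(chrom_bp, dtype=float) / self.bp_per_cm()


def simulate_genome(config: GenomeConfig) -> Genome:
    """Lay out scaffolds and SNP sites on a uniform cM<->bp genome.

    SNP counts per chromosome are Poisson with mean
    ``snp_density * chrom_length_bp``; marker types are drawn i.i.d.
    from ``marker_type_weights``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    bases = np.array(list("ACGT"))
    w = np.asarray(config.marker_type_weights, dtype=float)
    type_p = w / w.sum()
    type_labels = np.array([P1HET, P2HET, BOTHHET])

    site_rows = []
    scaff_rows = []
    for c in range(1, config.n_chromosomes + 1):
        lbp = config.chrom_length_bp
        n_snp = rng.poisson(config.snp_density * lbp)
        pos = np.sort(rng.choice(lbp, size=min(n_snp, lbp), replace=False)) + 1
        mtype = type_labels[rng.choice(3, size=pos.size, p=type_p)]
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4

        n_breaks = rng.poisson(config.scaffold_break_rate)
        breaks = np.sort(rng.integers(1, lbp, size=n_breaks))
        bounds = np.concatenate([[0], breaks, [lbp]])
        # drop zero-length scaffold pieces from coincident breaks
        bounds = np.unique(bounds)
        scaff_of_site = np.searchsorted(bounds, pos, side="left") - 1
        for k in range(len(bounds) - 1):
            name = f"scf{c:02d}_{k:02d}"
            scaff_rows.append(
                {"chrom": c, "scaffold": name,
                 "start_bp": int(bounds[k]) + 1, "end_bp": int(bounds[k + 1])}
            )
        scaff_names = np.array(
            [f"scf{c:02d}_{k:02d}" for k in range(len(bounds) - 1)]
        )
        site_rows.append(
            pd.DataFrame(
                {
                    "chrom": c,
                    "chrom_bp": pos,
                    "cm": pos / lbp * config.chrom_length_cm,
                    "scaffold": scaff_names[scaff_of_site],
                    "pos": pos - bounds[scaff_of_site].astype(int),
                    "marker_type": mtype,
                    "ref": bases[ref_i],
                    "alt": bases[alt_i],
                }
            )
        )
    sites = pd.concat(site_rows, ignore_index=True)
    scaffolds = pd.DataFrame(scaff_rows)
    return Genome(config=config, sites=sites, scaffolds=scaffolds)


# ----------------------------------------------------------------------
@dataclass
class CrossTruth:
    """Meiosis truth for every progeny gamete.

    ``crossovers[(parent, chrom)][i]`` is the sorted array of crossover
    positions (cM) of individual *i*'s gamete from that parent, and
    ``start_hap`` the founder haplotype (0/1) transmitted at position 0.
    """

    genome: Genome
    individuals: list[str]
    crossovers: dict[tuple[str, int], list[np.ndarray]]
    start_hap: dict[tuple[str, int], np.ndarray]

    @property
    def n_progeny(self) -> int:
        return len(self.individuals)

    def hap_at(self, parent: str, chrom: int, cm: np.ndarray) -> np.ndarray:
        """Transmitted founder haplotype (0/1) at cM positions.

        Returns an array of shape (len(cm), n_progeny).
        """
        cm = np.asarray(cm, dtype=float)
        out = np.empty((cm.size, self.n_progeny), dtype=np.int8)
        xo = self.crossovers[(parent, chrom)]
        sh = self.start_hap[(parent, chrom)]
        for i in range(self.n_progeny):
            out[:, i] = (sh[i] + np.searchsorted(xo[i], cm)) % 2
        return out

    def transmitted_states(self, parent: str) -> np.ndarray:
        """True transmitted allele (0=A, 1=B) at every genome site.

        At sites where *parent* is homozygous the transmitted allele is
        always the reference allele (0).
        """
        sites = self.genome.sites
        out = np.zeros((len(sites), self.n_progeny), dtype=np.int8)
        het_type = P1HET if parent == "P1" else P2HET
        for c, idx in sites.groupby("chrom", sort=True).indices.items():
            hap = self.hap_at(parent, int(c), sites["cm"].to_numpy()[idx])
            mt = sites["marker_type"].to_numpy()[idx]
            het = (mt == het_type) | (mt == BOTHHET)
            hap[~het, :] = 0
            out[idx, :] = hap
        return out

    def true_genotypes(self) -> np.ndarray:
        """True progeny genotype codes (AA/AB/BB) at every genome site."""
        return (self.transmitted_states("P1") + self.transmitted_states("P2")).astype(np.int8)

    def crossover_table(self) -> pd.DataFrame:
        rows = []
        bp_per_cm = self.genome.bp_per_cm()
        for (parent, chrom), xos in self.crossovers.items():
            for i, arr in enumerate(xos):
                for cm in arr:
                    rows.append(
                        {"individual": self.individuals[i], "parent": parent,
                         "chrom": chrom, "cm": float(cm),
                         "chrom_bp": int(round(cm * bp_per_cm))}
                    )
        df = pd.DataFrame(rows, columns=["individual", "parent", "chrom", "cm", "chrom_bp"])
        return df.sort_values(["parent", "chrom", "individual", "cm"]).reset_index(drop=True)


def _gamete_crossovers(rng, length_cm: float, interference: str, shape: float) -> np.ndarray:
    if interference == "none":
        k = rng.poisson(length_cm / 100.0)
        return np.sort(rng.uniform(0.0, length_cm, size=k))
    if interference == "gamma":
        # gamma-renewal crossover process; burn-in approximates stationarity
        burn = 500.0
        t = -burn
        pts = []
        scale = 100.0 / shape
        while t < length_cm:
            t += rng.gamma(shape, scale)
            if 0.0 <= t < length_cm:
                pts.append(t)
        return np.asarray(pts)
    raise ConfigurationError(f"unknown interference mode {interference!r}")


def simulate_cross(
    genome: Genome,
    n_progeny: int = DEFAULT_N_PROGENY,
    interference: str = "none",
    interference_shape: float = 2.5,
    seed: int | None = None,
) -> CrossTruth:
    """Simulate gametes for every progeny from both parents.

    Under ``interference='none'`` crossovers are a Poisson process with
    mean L/100 per gamete on a chromosome of L centimorgan (Haldane
    model); ``'gamma'`` gives a gamma-renewal process with positive
    interference.
    """
    if n_progeny < 1:
        raise ConfigurationError("n_progeny must be >= 1")
    rng = np.random.default_rng(genome.config.seed + 1 if seed is None else seed)
    individuals = [f"P{i + 1:03d}" for i in range(n_progeny)]
    crossovers: dict[tuple[str, int], list[np.ndarray]] = {}
    start_hap: dict[tuple[str, int], np.ndarray] = {}
    L = genome.config.chrom_length_cm
    for parent in ("P1", "P2"):
        for c in range(1, genome.config.n_chromosomes + 1):
            crossovers[(parent, c)] = [
                _gamete_crossovers(rng, L, interference, interference_shape)
                for _ in range(n_progeny)
            ]
            start_hap[(parent, c)] = rng.integers(0, 2, size=n_progeny).astype(np.int8)
    return CrossTruth(genome=genome, individuals=individuals,
                      crossovers=crossovers, start_hap=start_hap)


# ----------------------------------------------------------------------
@dataclass
class ObservationModel:
    """Low-coverage genotype observation model.

    Per site and individual, read depth is gamma-Poisson (negative
    binomial) with mean ``mean_depth`` (parents multiplied by
    ``parent_depth_multiplier``) and dispersion ``depth_dispersion``
    (None for pure Poisson).  Each read reports the wrong allele with
    probability ``base_error``.  Calls: depth below ``min_call_depth``
    is MISSING; heterozygous iff the minor allele has at least
    ``het_min_minor`` reads; otherwise the majority homozygote.
    """

    mean_depth: float = 20.0
    depth_dispersion: float | None = 6.0
    base_error: float = 0.0013
    min_call_depth: int = 3
    het_min_minor: int = 2
    parent_depth_multiplier: float = 3.0

    def validate(self) -> None:
        if not (0 <= self.base_error < 0.5):
            raise ConfigurationError("base_error must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ConfigurationError("mean_depth must be positive")

    def het_miscall_prob_at_hom(self, depth: int) -> float:
        """Analytic P(heterozygous call | homozygous truth, given depth)."""
        e = self.base_error
        p = 0.0
        for b in range(self.het_min_minor, depth - self.het_min_minor + 1):
            p += math.comb(depth, b) * e**b * (1 - e) ** (depth - b)
        return p


def _sample_depth(rng, mean, dispersion, size):
    if mean == math.inf:
        raise ValueError("depth must be finite when sampling")
    if dispersion is None:
        return rng.poisson(mean, size=size)
    lam = rng.gamma(dispersion, mean / dispersion, size=size)
    return rng.poisson(lam)


def _call_from_counts(depth, alt_count, model: ObservationModel) -> np.ndarray:
    ref_count = depth - alt_count
    minor = np.minimum(ref_count, alt_count)
    calls = np.where(alt_count > ref_count, BB, AA).astype(np.int8)
    calls[minor >= model.het_min_minor] = AB
    calls[depth < model.min_call_depth] = MISSING
    return calls


def _genotype_quality(depth, alt_count, model: ObservationModel, calls) -> np.ndarray:
    """Phred-scaled confidence of the called genotype vs the best other."""
    e = max(model.base_error, 1e-6)
    # log10 likelihoods under binomial allele sampling for AA/AB/BB
    with np.errstate(divide="ignore", invalid="ignore"):
        l_aa = alt_count * math.log10(e) + (depth - alt_count) * math.log10(1 - e)
        l_ab = depth * math.log10(0.5)
        l_bb = (depth - alt_count) * math.log10(e) + alt_count * math.log10(1 - e)
    ls = np.stack([l_aa, l_ab, l_bb], axis=0)
    called = np.clip(calls, 0, 2)
    l_called = np.take_along_axis(ls, called[None, ...], axis=0)[0]
    ls_masked = ls.copy()
    np.put_along_axis(ls_masked, called[None, ...], -np.inf, axis=0)
    l_second = ls_masked.max(axis=0)
    gq = np.clip(np.rint(10.0 * (l_called - l_second)), 0, 99).astype(np.int16)
    gq[calls == MISSING] = 0
    return gq


def observe_genotypes(
    truth: CrossTruth,
    model: ObservationModel | None = None,
    seed: int | None = None,
) -> SnpMatrix:
    """Sample noisy observed genotypes for parents and progeny.

    Returns a :class:`SnpMatrix` keyed by scaffold coordinates, with
    per-call depth and genotype quality, ready for VCF export or
    direct filtering.
    """
    model = model or ObservationModel()
    model.validate()
    rng = np.random.default_rng(truth.genome.config.seed + 2 if seed is None else seed)
    sites = truth.genome.sites
    n_sites = len(sites)
    samples = ["P1", "P2"] + truth.individuals
    n_samples = len(samples)

    # true genotype codes per site per sample
    g = np.empty((n_sites, n_samples), dtype=np.int8)
    mt = sites["marker_type"].to_numpy()
    g[:, 0] = np.where((mt == P1HET) | (mt == BOTHHET), AB, AA)
    g[:, 1] = np.where((mt == P2HET) | (mt == BOTHHET), AB, AA)
    g[:, 2:] = truth.true_genotypes()

    means = np.full(n_samples, model.mean_depth)
    means[:2] *= model.parent_depth_multiplier
    if math.isinf(model.mean_depth):
        # noise-free limiting case used in tests: calls equal truth
        depth = np.full((n_sites, n_samples), 10**6, dtype=np.int64)
        calls = g.copy()
        gq = np.full((n_sites, n_samples), 99, dtype=np.int16)
    else:
        depth = np.empty((n_sites, n_samples), dtype=np.int64)
        for j in range(n_samples):
            depth[:, j] = _sample_depth(rng, means[j], model.depth_dispersion, n_sites)
        p_alt = np.choose(g, [model.base_error, 0.5, 1.0 - model.base_error])
        alt_count = rng.binomial(depth, p_alt)
        calls = _call_from_counts(depth, alt_count, model)
        gq = _genotype_quality(depth, alt_count, model, calls)

    mean_depth = depth.mean(axis=1)
    site_table = pd.DataFrame(
        {
            "scaffold": sites["scaffold"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "ref": sites["ref"].to_numpy(),
            "alt": sites["alt"].to_numpy(),
            "qual": np.round(50.0 + mean_depth, 1),
            "mean_depth": mean_depth,
        }
    )
    return SnpMatrix(sites=site_table, calls=calls, samples=samples,
                     parents=("P1", "P2"), depth=depth, gq=gq)


def write_vcf(matrix: SnpMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a standard VCF 4.2 file with GT:DP:GQ sample fields."""
    gt_map = {AA: "0/0", AB: "0/1", BB: "1/1", MISSING: "./."}
    scaffs = list(pd.unique(matrix.sites["scaffold"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bluebin-simulator\n")
        for s in scaffs:
            if contig_lengths and s in contig_lengths:
                fh.write(f"##contig=<ID={s},length={contig_lengths[s]}>\n")
            else:
                fh.write(f"##contig=<ID={s}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        depth = matrix.depth
        gq = matrix.gq
        sites = matrix.sites
        for i in range(matrix.n_sites):
            fields = [
                str(sites["scaffold"].iat[i]), str(int(sites["pos"].iat[i])), ".",
                str(sites["ref"].iat[i]), str(sites["alt"].iat[i]),
                f"{float(sites['qual'].iat[i]):g}", "PASS", ".", "GT:DP:GQ",
            ]
            for j in range(matrix.n_samples):
                d = 0 if depth is None else int(depth[i, j])
                q = 0 if gq is None else int(gq[i, j])
                fields.append(f"{gt_map[int(matrix.calls[i, j])]}:{d}:{q}")
            fh.write("\t".join(fields) + "\n")


# ----------------------------------------------------------------------
@dataclass
class Qtl:
    """One additive QTL: effects are per parental gamete (added to the
    phenotype when the individual inherited founder haplotype 1)."""

    chrom: int
    cm: float
    effect_p1: float = 0.0
    effect_p2: float = 0.0


@dataclass
class TraitSpec:
    """A trait with known QTL architecture and target heritability."""

    name: str = "trait"
    qtls: list[Qtl] = field(default_factory=list)
    h2_target: float = 0.8
    n_years: int = 2
    n_reps: int = 3  # clone replicates per genotype per year

    def validate(self, genome: Genome) -> None:
        if not (0 < self.h2_target <= 1):
            if self.h2_target == 0 and any(
                q.effect_p1 or q.effect_p2 for q in self.qtls
            ):
                raise ConfigurationError("h2_target 0 with nonzero QTL effects")
            raise ConfigurationError("h2_target must be in (0, 1]")
        for q in self.qtls:
            if not (1 <= q.chrom <= genome.config.n_chromosomes):
                raise ConfigurationError(f"QTL chromosome {q.chrom} outside genome")
            if not (0 <= q.cm <= genome.config.chrom_length_cm):
                raise ConfigurationError(f"QTL position {q.cm} cM outside map")


def genetic_values(truth: CrossTruth, spec: TraitSpec) -> np.ndarray:
    """True genetic value per individual under the additive QTL model."""
    g = np.zeros(truth.n_progeny)
    for q in spec.qtls:
        pos = np.array([q.cm])
        if q.effect_p1:
            g += q.effect_p1 * truth.hap_at("P1", q.chrom, pos)[0]
        if q.effect_p2:
            g += q.effect_p2 * truth.hap_at("P2", q.chrom, pos)[0]
    return g


def simulate_traits(
    truth: CrossTruth,
    specs: list[TraitSpec] | TraitSpec,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate clone-replicated phenotypes for one or more traits.

    Environmental noise is scaled so that the per-plot broad-sense
    heritability Vg/(Vg+Ve) matches ``h2_target`` given the realized
    genetic variance.  Returns a long phenotype table
    (individual, trait, year, rep, value) and a truth table of genetic
    values per individual per trait.
    """
    if isinstance(specs, TraitSpec):
        specs = [specs]
    rng = np.random.default_rng(truth.genome.config.seed + 3 if seed is None else seed)
    rows = []
    truth_rows = {}
    for spec in specs:
        spec.validate(truth.genome)
        g = genetic_values(truth, spec)
        truth_rows[spec.name] = g
        vg = float(np.var(g))
        if vg == 0.0:
            sigma = 1.0
        else:
            sigma = math.sqrt(vg * (1.0 - spec.h2_target) / spec.h2_target)
        for year in range(1, spec.n_years + 1):
            eps = rng.normal(0.0, sigma, size=(truth.n_progeny, spec.n_reps))
            for r in range(spec.n_reps):
                for i, ind in enumerate(truth.individuals):
                    rows.append(
                        (ind, spec.name, f"Y{year}", r + 1, g[i] + eps[i, r])
                    )
    pheno = pd.DataFrame(rows, columns=["individual", "trait", "year", "rep", "value"])
    gtable = pd.DataFrame(truth_rows, index=truth.individuals)
    gtable.index.name = "individual"
    return pheno, gtable


def trait_year_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Clone means per individual for each trait-year column."""
    wide = pheno.pivot_table(index="individual", columns=["trait", "year"],
                             values="value", aggfunc="mean")
    wide.columns = [f"{t}_{y}" for t, y in wide.columns]
    return wide


def broad_sense_h2(pheno: pd.DataFrame, trait: str, year: str) -> float:
    """Estimate per-plot broad-sense heritability from clone replicates.

    One-way ANOVA across individuals: Vg = (MSB - MSW)/r,
    H2 = Vg / (Vg + MSW).
    """
    sub = pheno[(pheno["trait"] == trait) & (pheno["year"] == year)]
    groups = sub.groupby("individual")["value"]
    r = groups.size().iloc[0]
    means = groups.mean()
    grand = sub["value"].mean()
    k = len(means)
    msb = r * float(((means - grand) ** 2).sum()) / (k - 1)
    msw = float(groups.apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()) / (len(sub) - k)
    vg = max((msb - msw) / r, 0.0)
    return vg / (vg + msw) if (vg + msw) > 0 else 0.0
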