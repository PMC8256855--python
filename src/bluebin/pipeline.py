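"""End-to-end pipeline stages and file-based orchestration.

Each stage is a plain function over in-memory objects plus a writer of
tab-separated artifacts; :func:`run_pipeline` chains them and writes a
run manifest (all parameters, seed, input checksums) so that a rerun
with identical configuration reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import filtering, linkage, qtl, simulate, windows
from .config import PipelineConfig
from .core import MISSING, SnpMatrix

log = logging.getLogger(__name__)


def _subseed(seed: int, k: int) -> int:
    """Independent per-stage seed derived from the master seed."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


@dataclass
class SimulationBundle:
    genome: simulate.Genome
    truth: simulate.CrossTruth
    matrix: SnpMatrix
    phenotypes: pd.DataFrame
    genetic_values: pd.DataFrame


def stage_simulate(cfg: PipelineConfig) -> SimulationBundle:
    genome = simulate.simulate_genome(
        simulate.GenomeConfig(
            n_chromosomes=cfg.n_chromosomes,
            chrom_length_cm=cfg.chrom_length_cm,
            chrom_length_bp=cfg.chrom_length_bp,
            snp_density=cfg.snp_density,
            scaffold_break_rate=cfg.scaffold_break_rate,
            seed=_subseed(cfg.seed, 0),
        )
    )
    truth = simulate.simulate_cross(
        genome, n_progeny=cfg.n_progeny, interference=cfg.interference,
        seed=_subseed(cfg.seed, 1),
    )
    model = simulate.ObservationModel(
        mean_depth=cfg.mean_depth,
        depth_dispersion=cfg.depth_dispersion,
        base_error=cfg.base_error,
        min_call_depth=cfg.min_call_depth,
        het_min_minor=cfg.het_min_minor,
        parent_depth_multiplier=cfg.parent_depth_multiplier,
    )
    matrix = simulate.observe_genotypes(truth, model, seed=_subseed(cfg.seed, 2))
    specs = [
        simulate.TraitSpec(
            name=t.name,
            qtls=[simulate.Qtl(chrom=t.chrom, cm=t.cm,
                               effect_p1=t.effect_p1, effect_p2=t.effect_p2)],
            h2_target=t.h2, n_years=t.n_years, n_reps=t.n_reps,
        )
        for t in cfg.traits
    ]
    pheno, gvalues = simulate.simulate_traits(truth, specs, seed=_subseed(cfg.seed, 3))
    return SimulationBundle(genome, truth, matrix, pheno, gvalues)


def write_simulation(bundle: SimulationBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = dict(
        zip(bundle.genome.scaffolds["scaffold"],
            bundle.genome.scaffolds["end_bp"] - bundle.genome.scaffolds["start_bp"] + 1)
    )
    simulate.write_vcf(bundle.matrix, outdir / "population.vcf", contig_lengths=lengths)
    bundle.phenotypes.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    bundle.truth.crossover_table().to_csv(outdir / "truth_crossovers.tsv",
                                          sep="\t", index=False)
    bundle.genetic_values.to_csv(outdir / "truth_genetic_values.tsv", sep="\t")


def stage_filter(cfg: PipelineConfig, matrix: SnpMatrix):
    return filtering.full_filter(
        matrix,
        min_quality=cfg.min_quality,
        depth_range=(cfg.depth_min, cfg.depth_max),
        max_missing=cfg.max_missing,
        seg_alpha=cfg.seg_alpha,
        min_scored=cfg.min_scored,
    )


def write_filtered(matrix: SnpMatrix, report, seg_table: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_tsv(outdir / "filtered_sites.tsv", outdir / "genotype_matrix.tsv")
    report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)
    seg_table.to_csv(outdir / "segregation_tests.tsv", sep="\t", index=False)


def stage_binmap(cfg: PipelineConfig, matrix: SnpMatrix):
    w = cfg.window_size
    if w is None:
        # ladder selection on the parents' own call tracks at their
        # heterozygous sites (parents re-genotyped against themselves)
        i1, i2 = matrix.parent_indices
        tracks = []
        mt = matrix.sites["marker_type"].to_numpy()
        for parent_i, het in ((i1, "P1HET"), (i2, "P2HET")):
            for s, rows in matrix.scaffold_groups().items():
                sel = rows[(mt[rows] == het) | (mt[rows] == "BOTHHET")]
                if sel.size:
                    tracks.append(matrix.calls[sel, parent_i])
        w, _curve = windows.select_window_size(
            tracks, ladder=tuple(range(cfg.window_ladder_min, cfg.window_ladder_max + 1)))
    tracks, smoothed, breakpoints = windows.genotype_population(matrix, window_size=w)
    binset = windows.deduce_bins(matrix, tracks, smoothed)
    return tracks, smoothed, breakpoints, binset, w


def write_binmap(matrix: SnpMatrix, tracks, smoothed, breakpoints, binset, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    individuals = matrix.progeny
    block_rows = []
    for parent in ("P1", "P2"):
        for s, track in tracks[parent].items():
            sm = smoothed[parent][s]
            for j, ind in enumerate(individuals):
                for a, b, v in windows.blocks_from_states(sm[:, j]):
                    block_rows.append(
                        (ind, parent, s, int(track.pos_bp[a]), int(track.pos_bp[b]),
                         "A" if v == 0 else "B")
                    )
    pd.DataFrame(block_rows, columns=["individual", "parent", "scaffold",
                                      "start_bp", "end_bp", "state"]
                 ).to_csv(outdir / "blocks.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(b.individual, b.parent, b.scaffold, b.left_bp, b.right_bp, b.midpoint_bp)
         for b in breakpoints],
        columns=["individual", "parent", "scaffold", "left_bp", "right_bp", "midpoint_bp"],
    ).to_csv(outdir / "breakpoints.tsv", sep="\t", index=False)
    binset.genotype_table().to_csv(outdir / "bins.tsv", sep="\t", index=False)
    write_heat_grid(binset, outdir / "bin_heat_grid.txt")


def write_heat_grid(binset: windows.BinSet, path) -> None:
    """Plain-text QC grid: one row per bin, one column per track."""
    chars = np.array([".", "A", "B"])
    with open(path, "w") as fh:
        fh.write("# rows: marker bins; columns: individuals (P1 track block, "
                 "then P2 track block); . = missing\n")
        for i in range(binset.n_bins):
            row = "".join(chars[binset.states_p1[i] + 1]) + " " + "".join(
                chars[binset.states_p2[i] + 1])
            fh.write(f"{binset.bins['bin_id'].iat[i]}\t{row}\n")


def binset_from_genotype_table(df: pd.DataFrame) -> windows.BinSet:
    """Reconstruct a BinSet from a written bins.tsv table."""
    meta_cols = ["bin_id", "scaffold", "start_bp", "end_bp", "n_snps"]
    state_cols = [c for c in df.columns if c not in meta_cols]
    individuals = sorted({c.rsplit(".", 1)[0] for c in state_cols})
    code = {"A": 0, "B": 1}
    s1 = np.array([[code.get(v, MISSING) for v in df[f"{ind}.P1"]]
                   for ind in individuals]).T
    s2 = np.array([[code.get(v, MISSING) for v in df[f"{ind}.P2"]]
                   for ind in individuals]).T
    bins = df[meta_cols].copy()
    return windows.BinSet(bins=bins, states_p1=s1.astype(np.int8),
                          states_p2=s2.astype(np.int8), individuals=individuals)


def stage_map(cfg: PipelineConfig, binset: windows.BinSet) -> linkage.GeneticMap:
    return linkage.build_map(
        binset, rf_max=cfg.rf_max, lod_min=cfg.lod_min,
        min_informative=cfg.min_informative, rf_ceiling=cfg.rf_ceiling,
    )


def write_map(gmap: linkage.GeneticMap, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    gmap.table.to_csv(outdir / "map.tsv", sep="\t", index=False)
    summary = gmap.lg_summary()
    summary.to_csv(outdir / "map_lg_summary.tsv", sep="\t", index=False)
    totals = linkage.map_summary(summary)
    with open(outdir / "map_totals.tsv", "w") as fh:
        fh.write("statistic\tvalue\n")
        for k, v in totals.items():
            fh.write(f"{k}\t{v}\n")


def map_from_table(df: pd.DataFrame) -> linkage.GeneticMap:
    return linkage.GeneticMap(table=df, unplaced=np.empty(0, dtype=int))


def stage_qtl(
    cfg: PipelineConfig,
    gmap: linkage.GeneticMap,
    binset: windows.BinSet,
    phenotypes: pd.DataFrame,
    h2_by_trait: dict[str, float] | None = None,
):
    """Scan every trait-year column; returns (results, records table)."""
    means = simulate.trait_year_means(phenotypes)
    scan_cfg = qtl.ScanConfig(
        step_cm=cfg.step_cm, n_permutations=cfg.n_permutations,
        alpha=cfg.alpha, seed=_subseed(cfg.seed, 4), mode=cfg.qtl_mode,
        cofactor_window_cm=cfg.cofactor_window_cm,
    )
    results = []
    records = []
    engine_cache: dict[tuple[str, ...], qtl.ScanEngine] = {}
    for col in means.columns:
        trait, year = col.rsplit("_", 1)
        y = means[col].dropna()
        key = tuple(y.index)
        if key not in engine_cache:
            engine_cache[key] = qtl.ScanEngine(
                gmap, binset, individuals=list(y.index), step_cm=cfg.step_cm)
        h2 = (h2_by_trait or {}).get(trait)
        res = qtl.scan_trait(gmap, binset, y, scan_cfg, trait=trait, year=year,
                             h2=h2, engine=engine_cache[key])
        results.append(res)
        for p in res.peaks:
            records.append(
                {"trait": trait, "year": year, "lg": p.lg,
                 "bin_first": p.first_bin, "bin_last": p.last_bin,
                 "peak_cm": p.peak_cm, "peak_lod": p.peak_lod,
                 "threshold": res.threshold, "r2": p.r_squared,
                 "h2": h2, "r2_over_h2": p.r2_over_h2}
            )
    cols = ["trait", "year", "lg", "bin_first", "bin_last", "peak_cm",
            "peak_lod", "threshold", "r2", "h2", "r2_over_h2"]
    return results, pd.DataFrame(records, columns=cols)


def write_qtl(results, records: pd.DataFrame, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = []
    thresholds = []
    for res in results:
        p = res.profile.copy()
        p.insert(0, "year", res.year)
        p.insert(0, "trait", res.trait)
        profiles.append(p)
        thresholds.append((res.trait, res.year, res.threshold))
    pd.concat(profiles, ignore_index=True).to_csv(
        outdir / "lod_profiles.tsv", sep="\t", index=False)
    pd.DataFrame(thresholds, columns=["trait", "year", "threshold"]).to_csv(
        outdir / "thresholds.tsv", sep="\t", index=False)
    records.to_csv(outdir / "qtl_peaks.tsv", sep="\t", index=False)
    if len(records):
        supported, single = qtl.qtl_report(records)
    else:
        supported = single = pd.DataFrame()
    supported.to_csv(outdir / "qtl_supported.tsv", sep="\t", index=False)
    single.to_csv(outdir / "qtl_single_year.tsv", sep="\t", index=False)


def write_manifest(cfg: PipelineConfig, outdir: Path, inputs: dict[str, Path]) -> None:
    lines = [f"config.{k}={v}" for k, v in cfg.flat_items()]
    for name, path in sorted(inputs.items()):
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        lines.append(f"input.{name}.sha256={digest}")
    (outdir / "manifest.txt").write_text("\n".join(lines) + "\n")


def run_pipeline(cfg: PipelineConfig, outdir) -> dict:
    """Simulate, filter, bin-genotype, map and scan in one run.

    Writes the complete artifact set under *outdir* and returns the
    in-memory objects of every stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("simulating population")
    bundle = stage_simulate(cfg)
    write_simulation(bundle, outdir)

    log.info("filtering %d sites", bundle.matrix.n_sites)
    filtered, report, seg_table = stage_filter(cfg, bundle.matrix)
    write_filtered(filtered, report, seg_table, outdir)

    log.info("window genotyping %d sites", filtered.n_sites)
    tracks, smoothed, breakpoints, binset, w = stage_binmap(cfg, filtered)
    write_binmap(filtered, tracks, smoothed, breakpoints, binset, outdir)

    log.info("building map from %d bins", binset.n_bins)
    gmap = stage_map(cfg, binset)
    write_map(gmap, outdir)

    log.info("QTL scans")
    h2 = {t.name: t.h2 for t in cfg.traits}
    results, records = stage_qtl(cfg, gmap, binset, bundle.phenotypes, h2)
    write_qtl(results, records, outdir)

    write_manifest(cfg, outdir, {"vcf": outdir / "population.vcf"})
    return {
        "bundle": bundle, "filtered": filtered, "filter_report": report,
        "binset": binset, "breakpoints": breakpoints, "tracks": tracks,
        "smoothed": smoothed, "window_size": w, "map": gmap,
        "qtl_results": results, "qtl_records": records,
    }
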