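"""Pipeline configuration: one flat, YAML-serialisable record.

Collects every stage parameter — filter thresholds (quality 30, depth
3-750, missingness 50%, chi-square at alpha 0.05), window size 15 with
ladder 5-19, grouping at rf 0.35 / LOD 12, Kosambi distances, and the
scan settings (0.5 cM step, 10 cM cofactor window, 1000 permutations
at alpha 0.05).  The seed is mandatory for every stochastic stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml


@dataclass
class TraitConfig:
    name: str = "trait"
    chrom: int = 1
    cm: float = 50.0
    effect_p1: float = 1.0
    effect_p2: float = 0.0
    h2: float = 0.8
    n_years: int = 2
    n_reps: int = 3


def _default_traits() -> list[TraitConfig]:
    return [
        TraitConfig(name="ChillReqLike", chrom=5, cm=50.0, effect_p1=1.0,
                    h2=0.86, n_years=3),
        TraitConfig(name="ColdHardLike", chrom=10, cm=50.0, effect_p1=1.0,
                    h2=0.88, n_years=2),
    ]


@dataclass
class PipelineConfig:
    seed: int = 1
    log_level: str = "INFO"

    # genome & cross simulation
    n_chromosomes: int = 12
    chrom_length_cm: float = 100.0
    chrom_length_bp: int = 1_000_000
    snp_density: float = 4.08e-4  # 4.08 SNPs per 10 kbp
    scaffold_break_rate: float = 2.0
    n_progeny: int = 117
    interference: str = "none"

    # genotype observation
    mean_depth: float = 20.0
    depth_dispersion: float = 6.0
    base_error: float = 0.0013
    min_call_depth: int = 3
    het_min_minor: int = 2
    parent_depth_multiplier: float = 3.0

    # simulated traits
    traits: list[TraitConfig] = field(default_factory=_default_traits)

    # variant filtering
    min_quality: float = 30.0
    depth_min: float = 3.0
    depth_max: float = 750.0
    max_missing: float = 0.5
    seg_alpha: float = 0.05
    min_scored: int = 20

    # window genotyping
    window_size: int | None = 15  # None -> ladder selection
    window_ladder_min: int = 5
    window_ladder_max: int = 19

    # linkage mapping
    rf_max: float = 0.35
    lod_min: float = 12.0
    min_informative: int = 20
    rf_ceiling: float = 0.49

    # QTL scan
    step_cm: float = 0.5
    n_permutations: int = 1000
    alpha: float = 0.05
    qtl_mode: str = "im"
    cofactor_window_cm: float = 10.0

    # ------------------------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        traits = [TraitConfig(**t) for t in d.pop("traits", [])]
        cfg = PipelineConfig(**d)
        if traits:
            cfg.traits = traits
        return cfg

    def flat_items(self) -> list[tuple[str, str]]:
        """Sorted key=value view for the run manifest."""
        d = dataclasses.asdict(self)
        traits = d.pop("traits")
        items = [(k, repr(v)) for k, v in d.items()]
        for i, t in enumerate(traits):
            items.extend((f"trait{i}.{k}", repr(v)) for k, v in t.items())
        return sorted(items)
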