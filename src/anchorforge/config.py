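"""Configuration objects for the simulator and the pipeline.

All stochastic behaviour is driven by a single integer seed; every stage
derives its own child stream from it, so a config + seed pair fixes every
output bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml


class ConfigurationError(ValueError):
    """Raised for invalid simulator or pipeline configuration."""


@dataclass
class DistortionLocus:
    """A viability-selection locus causing segregation distortion.

    ``w_aa``/``w_ab``/``w_bb`` are relative survival probabilities of the
    three F2 genotype classes; an individual is accepted with probability
    ``w(genotype)/max(w)`` (rejection sampling), so e.g. ``(0.5, 1, 1)``
    halves the AA class and skews allele frequency toward the B parent.
    """

    chrom_index: int
    rel_pos: float  # fractional position along the chromosome, in (0, 1)
    w_aa: float = 1.0
    w_ab: float = 1.0
    w_bb: float = 1.0

    def validate(self) -> None:
        w = (self.w_aa, self.w_ab, self.w_bb)
        if min(w) < 0 or max(w) <= 0:
            raise ConfigurationError(f"invalid fitness triplet {w}")
        if not 0.0 < self.rel_pos < 1.0:
            raise ConfigurationError(f"rel_pos {self.rel_pos} outside (0,1)")


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic genome and F2 cross.

    The defaults emulate the melon re-anchoring design: a 12-chromosome
    (2n = 2x = 24) genome fragmented into sub-megabase scaffolds, a
    139-individual F2 intercross genotyped at a 580-SNP targeted panel,
    viability-driven segregation distortion on two chromosomes, injected
    chimeric scaffolds, >=2 centromeric satellite families per centromere
    and 45S/5S rDNA arrays. Physical sizes are scaled down (~8 Mb per
    chromosome) while per-chromosome map lengths stay realistic (~95 cM),
    so recombination statistics at n=139 match the real mapping regime.
    """

    n_chrom: int = 12
    chrom_length_mean: int = 8_000_000
    chrom_length_sd: int = 600_000
    chrom_map_length_cm: float = 95.0
    chrom_map_length_sd: float = 8.0
    centromere_span: int = 3_200_000
    centromere_slope: float = 0.05   # cM/Mb inside the centromeric plateau
    arm_asymmetry: float = 0.15      # relative slope difference between arms
    flat_slope: float | None = None  # force an exactly linear Marey curve

    scaffold_length_mean: int = 500_000
    scaffold_length_sigma: float = 0.45  # lognormal shape
    scaffold_min_length: int = 60_000
    contig_target_length: int = 350_000
    contig_gap_length: int = 100
    chimera_count: int = 2
    chimera_gap_length: int = 1_000
    flip_probability: float = 0.5    # chance a scaffold is assembled reversed

    n_individuals: int = 139
    n_markers: int = 580             # target panel size
    n_per_end: int = 2
    missing_rate: float = 0.03
    error_rate: float = 0.001
    distortion_loci: list[DistortionLocus] = field(
        default_factory=lambda: [
            DistortionLocus(0, 0.30, 0.5, 1.0, 1.0),
            DistortionLocus(3, 0.55, 0.55, 1.0, 1.0),
        ]
    )

    variant_spacing: int = 15_000    # mean bp between candidate variants
    genes_per_mb: float = 10.0
    rdna_45s_chroms: tuple[int, ...] = (0, 3)
    rdna_5s_chroms: tuple[int, ...] = (11,)

    seed: int = 0

    def validate(self) -> None:
        for name in ("missing_rate", "error_rate", "flip_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if self.n_chrom < 1:
            raise ConfigurationError("n_chrom must be >= 1")
        if self.chrom_length_mean <= 0 or self.chrom_length_sd < 0:
            raise ConfigurationError("invalid chromosome length distribution")
        if self.scaffold_length_mean < self.scaffold_min_length:
            raise ConfigurationError("scaffold mean below minimum length")
        if self.centromere_span >= self.chrom_length_mean:
            raise ConfigurationError("centromere span exceeds chromosome length")
        for locus in self.distortion_loci:
            locus.validate()
            if not 0 <= locus.chrom_index < self.n_chrom:
                raise ConfigurationError(
                    f"distortion locus on chromosome {locus.chrom_index} "
                    f"but genome has {self.n_chrom}"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["distortion_loci"] = [dataclasses.asdict(x) for x in self.distortion_loci]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        loci = [DistortionLocus(**x) for x in d.pop("distortion_loci", [])]
        for k in ("rdna_45s_chroms", "rdna_5s_chroms"):
            if k in d:
                d[k] = tuple(d[k])
        cfg = cls(distortion_loci=loci, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """End-to-end run settings wrapping a :class:`SimConfig` plus the
    thresholds of each analysis stage (all printed defaults of the method)."""

    sim: SimConfig = field(default_factory=SimConfig)

    # SNP selection
    quality_ladder: tuple[tuple[float, float], ...] = ((999, 15), (200, 10), (50, 8))
    flank_bp: int = 50
    end_window_frac: float = 0.20
    end_window_cap: int = 500_000

    # genotype QC
    min_call_rate: float = 0.85
    min_q1: float = 0.4
    min_q2: float = 0.2
    alpha_extreme: float = 0.0001
    alpha_flag: float = 0.05
    max_group_missing: float = 0.10

    # linkage mapping
    lod_threshold: float = 10.0
    map_function: str = "haldane"

    # pseudomolecules
    spacer: int = 1_000

    # recombination landscape
    window_mb: float = 1.0
    step_mb: float = 0.1
    suppress_threshold: float = 0.5  # cM/Mb
    min_zone_span_mb: float = 2.0

    # centromere calling
    min_coverage: float = 0.80
    min_identity: float = 0.80
    cluster_gap: int = 500_000
    require_psat107: bool = False
    rdna_merge_gap: int = 100_000

    qc_enabled: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["quality_ladder"] = [list(x) for x in self.quality_ladder]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = SimConfig.from_dict(d.pop("sim", {}))
        if "quality_ladder" in d:
            d["quality_ladder"] = tuple(tuple(x) for x in d["quality_ladder"])
        return cls(sim=sim, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
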