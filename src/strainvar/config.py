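"""Parameter blocks for every pipeline stage.

Each stage has a small frozen-ish dataclass holding its tunables with the
defaults used throughout: the calling cascade (minimum supporting calls,
support fractions, heterozygosity band), the read-depth CNV rules, the
annotation geometry (splice-region widths, gene flanks), the comparison
windows, and the simulator's genome/noise model.  ``PipelineConfig``
aggregates them and can be read from a TOML file with strict unknown-key
rejection.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


class ConfigurationError(ValueError):
    """Raised when a parameter violates its stated bounds."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass
class SimulationConfig:
    """Genome and noise model for the synthetic-data generator.

    chromosome_lengths
        Length in bp of each simulated chromosome (named chr1, chr2, ...).
    snv_rate / indel_rate
        Per-bp probability that a strain differs from the reference by a
        SNV / short indel.
    indel_max_len
        Longest simulated indel; kept below 10 bp (short indels).
    median_coverage
        Poisson mean of the duplicate-free per-site depth.
    per_base_error
        Probability a read base is miscalled (to a uniform other base).
    duplicate_fraction
        Probability a read is a start-position duplicate of another read;
        duplicates inflate raw depth but never the duplicate-free counts.
    het_site_fraction
        Per-bp rate of residual heterozygous sites (~50/50 allele mix),
        emulating loci not yet fixed by inbreeding.
    read_length
        Read length in bp, used to convert read starts to coverage.
    """

    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    snv_rate: float = 1e-3
    indel_rate: float = 1e-4
    indel_max_len: int = 9
    median_coverage: float = 20.0
    per_base_error: float = 0.01
    duplicate_fraction: float = 0.05
    het_site_fraction: float = 0.001
    read_length: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        _check(len(self.chromosome_lengths) >= 1, "need at least one chromosome")
        for name, length in self.chromosome_lengths.items():
            _check(int(length) >= 1, f"chromosome {name} has non-positive length")
        for attr in (
            "snv_rate",
            "indel_rate",
            "per_base_error",
            "duplicate_fraction",
            "het_site_fraction",
        ):
            value = getattr(self, attr)
            _check(0.0 <= value <= 1.0, f"{attr}={value} outside [0, 1]")
        _check(self.median_coverage >= 1, "median_coverage must be >= 1")
        _check(1 <= self.indel_max_len < 10, "indel_max_len must be in [1, 9]")
        _check(self.read_length >= 1, "read_length must be >= 1")


@dataclass
class CallingParams:
    """Filter cascade for SNV/indel calling from pileups.

    A variant is called when at least ``min_calls`` duplicate-free reads
    with base quality > ``min_call_quality`` support the dominant
    non-reference allele and the supporting fraction of the duplicate-free
    depth reaches ``min_support_snv`` (``min_support_indel`` for indels).
    Sites with intermediate support (the ``het_band``) are excluded as
    residual heterozygosity, inconsistent with inbred homozygosity.
    Calls at sites with depth >= ``hq_min_coverage`` form the
    high-quality set.
    """

    min_calls: int = 3
    min_call_quality: int = 10
    min_support_snv: float = 0.75
    min_support_indel: float = 0.40
    het_band: tuple[float, float] = (0.25, 0.75)
    hq_min_coverage: int = 8
    indel_max_len: int = 9

    def __post_init__(self) -> None:
        _check(self.min_calls >= 1, "min_calls must be >= 1")
        _check(
            0.0 < self.min_support_indel <= self.min_support_snv <= 1.0,
            "need 0 < min_support_indel <= min_support_snv <= 1",
        )
        lo, hi = self.het_band
        _check(0.0 <= lo < hi <= 1.0, "het_band must be a sub-interval of [0, 1]")
        _check(self.hq_min_coverage >= 1, "hq_min_coverage must be >= 1")
        _check(1 <= self.indel_max_len < 10, "indel_max_len must be in [1, 9]")


@dataclass
class CnvParams:
    """Read-depth-ratio CNV detection between two strains.

    Windows hold a fixed count of strain-A read starts
    (``reads_per_window``), so window size adapts to local coverage.
    Normalized count ratios below ``del_ratio`` / above ``dup_ratio``
    seed deletion / duplication events.  Calls are kept only when at
    least one strain's mean coverage in the call lies within
    ``coverage_band`` x (its genome mean); deletions additionally
    require the fractions of uncovered bases in the two strains to
    differ by at least ``uncovered_diff`` percentage points.
    """

    reads_per_window: int = 500
    del_ratio: float = 0.3
    dup_ratio: float = 1.6
    coverage_band: float = 0.5
    uncovered_diff: float = 10.0
    min_event_windows: int = 2
    read_length: int = 50

    def __post_init__(self) -> None:
        _check(
            0.0 < self.del_ratio < 1.0 < self.dup_ratio,
            "need 0 < del_ratio < 1 < dup_ratio",
        )
        _check(0.0 < self.coverage_band <= 1.0, "coverage_band must be in (0, 1]")
        _check(0.0 <= self.uncovered_diff <= 100.0, "uncovered_diff is in [0, 100]")
        _check(self.reads_per_window >= 1, "reads_per_window must be >= 1")
        _check(self.min_event_windows >= 1, "min_event_windows must be >= 1")


@dataclass
class AnnotationParams:
    """Geometry of the consequence classifier.

    essential_splice_bp: intronic bases at each exon boundary that are
    essential splice sites (the canonical GT/AG dinucleotides).
    splice_exon_bp / splice_intron_bp: the wider splice region on the
    exonic / intronic side.  flank_bp: distance over which a variant
    outside a gene is upstream/downstream rather than intergenic.
    """

    essential_splice_bp: int = 2
    splice_exon_bp: int = 3
    splice_intron_bp: int = 8
    flank_bp: int = 5000
    conservation_threshold: float = 0.1

    def __post_init__(self) -> None:
        _check(self.essential_splice_bp >= 0, "essential_splice_bp must be >= 0")
        _check(self.flank_bp >= 0, "flank_bp must be >= 0")
        _check(
            0.0 <= self.conservation_threshold <= 1.0,
            "conservation_threshold must be in [0, 1]",
        )


@dataclass
class ComparisonParams:
    """Multi-strain sharing and differentiating-region parameters.

    The sharing partition drops positions where any strain is
    heterozygous-excluded or covered by fewer than
    ``sharing_min_coverage`` reads.  Differentiating regions between two
    sub-strains are windows of ``region_window`` bp whose density of
    genotype-differing positions (both strains covered by at least
    ``region_min_coverage`` reads) exceeds ``region_density_per_mbp``;
    runs of such windows merge across gaps of up to
    ``region_merge_gap`` windows.
    """

    sharing_min_coverage: int = 3
    region_window: int = 100_000
    region_density_per_mbp: float = 100.0
    region_min_coverage: int = 8
    region_merge_gap: int = 1
    ancestry_tie_margin: float = 0.02

    def __post_init__(self) -> None:
        _check(self.sharing_min_coverage >= 0, "sharing_min_coverage must be >= 0")
        _check(self.region_window >= 1, "region_window must be >= 1")
        _check(self.region_density_per_mbp > 0, "region_density_per_mbp must be > 0")
        _check(0.0 <= self.ancestry_tie_margin <= 1.0, "tie margin must be in [0, 1]")


@dataclass
class EnrichmentParams:
    """Gene-level enrichment testing of variant features vs expression."""

    alpha: float = 0.05
    de_thresholds: tuple[float, ...] = (2.0, 1.7, 1.5)
    splice_thresholds: tuple[float, ...] = (1e-5, 1e-2, 1e-1)

    def __post_init__(self) -> None:
        _check(0.0 < self.alpha < 1.0, "alpha must be in (0, 1)")


_SECTIONS: dict[str, type] = {
    "simulation": SimulationConfig,
    "calling": CallingParams,
    "cnv": CnvParams,
    "annotation": AnnotationParams,
    "comparison": ComparisonParams,
    "enrichment": EnrichmentParams,
}


@dataclass
class PipelineConfig:
    """Aggregate configuration for an end-to-end run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calling: CallingParams = field(default_factory=CallingParams)
    cnv: CnvParams = field(default_factory=CnvParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    comparison: ComparisonParams = field(default_factory=ComparisonParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    n_strains: int = 4
    seed: int = 0
    output_dir: str = "strainvar_out"

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Read a config file, rejecting unknown sections and keys."""
        with open(path, "rb") as fh:
            raw: dict[str, Any] = tomllib.load(fh)
        kwargs: dict[str, Any] = {}
        top_fields = {f.name for f in dataclasses.fields(cls)}
        for key, value in raw.items():
            if key in _SECTIONS:
                section_cls = _SECTIONS[key]
                allowed = {f.name for f in dataclasses.fields(section_cls)}
                unknown = set(value) - allowed
                if unknown:
                    raise ConfigurationError(
                        f"unknown keys in [{key}]: {sorted(unknown)}"
                    )
                if key == "simulation" and "chromosome_lengths" in value:
                    value["chromosome_lengths"] = {
                        str(k): int(v) for k, v in value["chromosome_lengths"].items()
                    }
                if key == "calling" and "het_band" in value:
                    value["het_band"] = tuple(value["het_band"])
                kwargs[key] = section_cls(**value)
            elif key in top_fields:
                kwargs[key] = value
            else:
                raise ConfigurationError(f"unknown config key: {key}")
        return cls(**kwargs)
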