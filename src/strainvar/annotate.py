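"""Variant consequence classification against gene models.

A simplified, transparent consequence classifier with twelve mutually
exclusive categories per (variant, transcript), ordered by severity:

    stop_gained > stop_lost > non_synonymous > synonymous >
    essential_splice_site > splice_site > utr5 > utr3 > intronic >
    upstream > downstream > intergenic

Coding SNVs are classified by strand-aware codon translation.
Essential splice sites are the first/last two intronic bases of each
intron; the wider splice region spans 3 bases on the exon side and 8 on
the intron side of each junction (coding consequences take precedence
on the exon side).  Variants outside all transcripts but within a
configurable flank are upstream/downstream of the gene by strand.
Conservation flags use a phastCons-like per-base score in [0, 1];
a variant is conserved iff its score is strictly greater than the
threshold (default 0.1), with missing positions scoring 0.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from Bio.Seq import Seq

from strainvar.config import AnnotationParams
from strainvar.calling import VariantCall, VariantClass


class Category(str, Enum):
    STOP_GAINED = "stop_gained"
    STOP_LOST = "stop_lost"
    NON_SYNONYMOUS = "non_synonymous"
    SYNONYMOUS = "synonymous"
    ESSENTIAL_SPLICE_SITE = "essential_splice_site"
    SPLICE_SITE = "splice_site"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


#: severity order, most severe first
SEVERITY: list[Category] = list(Category)

CODING_CATEGORIES = {
    Category.STOP_GAINED,
    Category.STOP_LOST,
    Category.NON_SYNONYMOUS,
    Category.SYNONYMOUS,
}
SPLICE_CATEGORIES = {Category.ESSENTIAL_SPLICE_SITE, Category.SPLICE_SITE}
UTR_CATEGORIES = {Category.UTR5, Category.UTR3}


def severity_rank(category: Category) -> int:
    return SEVERITY.index(category)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: list[tuple[int, int]]  # 0-based half-open, ascending, non-overlapping
    cds: list[tuple[int, int]] = field(default_factory=list)  # subset of exons

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {s1}-{e1}, {s2}-{e2}"
                )
        for s, e in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise ValueError(
                    f"{self.transcript_id}: CDS {s}-{e} not contained in an exon"
                )
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_s1, e1), (s2, _e2) in zip(self.exons, self.exons[1:])
        ]

    def cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position within the spliced CDS,
        counted in translation order (strand-aware)."""
        offset = 0
        segments = self.cds if self.strand == "+" else list(reversed(self.cds))
        for s, e in segments:
            if s <= pos < e:
                return offset + (pos - s if self.strand == "+" else e - 1 - pos)
            offset += e - s
        return None

    def cds_sequence(self, chrom_seq: str) -> str:
        parts = [chrom_seq[s:e] for s, e in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


@dataclass(frozen=True)
class Consequence:
    category: Category
    gene_id: str
    transcript_id: str | None = None
    note: str = ""


class ConservationTrack:
    """Per-position conservation scores; positions not covered score 0."""

    def __init__(self, intervals: dict[str, list[tuple[int, int, float]]]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._scores: dict[str, list[float]] = {}
        for chrom, rows in intervals.items():
            rows = sorted(rows)
            for (s1, e1, _v1), (s2, _e2, _v2) in zip(rows, rows[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping conservation intervals on {chrom}")
            for _s, _e, v in rows:
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"conservation score {v} outside [0, 1]")
            self._starts[chrom] = [s for s, _e, _v in rows]
            self._ends[chrom] = [e for _s, e, _v in rows]
            self._scores[chrom] = [v for _s, _e, v in rows]

    def score_at(self, chrom: str, pos: int) -> float:
        starts = self._starts.get(chrom)
        if not starts:
            return 0.0
        i = bisect.bisect_right(starts, pos) - 1
        if i >= 0 and pos < self._ends[chrom][i]:
            return self._scores[chrom][i]
        return 0.0

    def intervals(self) -> dict[str, list[tuple[int, int, float]]]:
        return {
            chrom: list(zip(self._starts[chrom], self._ends[chrom], self._scores[chrom]))
            for chrom in self._starts
        }


def is_conserved(
    variant: VariantCall,
    track: ConservationTrack,
    threshold: float = 0.1,
) -> bool:
    """Strictly-greater-than rule: score must exceed the threshold."""
    return track.score_at(variant.chrom, variant.pos) > threshold


def _codon_consequence(
    tx: TranscriptModel, variant: VariantCall, chrom_seq: str
) -> tuple[Category, str]:
    """Classify a CDS-overlapping variant by codon translation."""
    if variant.variant_class is not VariantClass.SNV:
        length_change = abs(len(variant.alt) - len(variant.ref))
        note = "frameshift" if length_change % 3 else "inframe"
        return Category.NON_SYNONYMOUS, note
    idx = tx.cds_index(variant.pos)
    assert idx is not None
    cds_seq = tx.cds_sequence(chrom_seq)
    codon_i = idx // 3
    within = idx % 3
    ref_codon = cds_seq[3 * codon_i : 3 * codon_i + 3]
    alt_base = variant.alt
    if tx.strand == "-":
        alt_base = str(Seq(alt_base).complement())
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == "*" and ref_aa != "*":
        return Category.STOP_GAINED, ""
    if ref_aa == "*" and alt_aa != "*":
        return Category.STOP_LOST, ""
    if ref_aa == alt_aa:
        return Category.SYNONYMOUS, ""
    return Category.NON_SYNONYMOUS, ""


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _classify_in_transcript(
    tx: TranscriptModel,
    variant: VariantCall,
    chrom_seq: str,
    params: AnnotationParams,
) -> Category | None:
    """Category of a variant inside the transcript span, else None."""
    pos = variant.pos
    if not tx.start <= pos < tx.end:
        return None
    in_exon = _in_any(pos, tx.exons)
    if in_exon:
        if _in_any(pos, tx.cds) or (
            variant.variant_class is not VariantClass.SNV
            and _spans_cds(variant, tx)
        ):
            return None  # handled by the coding path
        # splice region on the exon side of an internal junction
        for intron_start, intron_end in tx.introns:
            if 0 < intron_start - pos <= params.splice_exon_bp:
                return Category.SPLICE_SITE
            if 0 < pos - intron_end + 1 <= params.splice_exon_bp:
                return Category.SPLICE_SITE
        if not tx.cds:
            return Category.INTRONIC  # non-coding transcript body
        cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
        if pos < cds_start:
            return Category.UTR5 if tx.strand == "+" else Category.UTR3
        if pos >= cds_end:
            return Category.UTR3 if tx.strand == "+" else Category.UTR5
        return Category.INTRONIC
    # intronic position: distance (1-based) into the intron from each edge
    for intron_start, intron_end in tx.introns:
        if intron_start <= pos < intron_end:
            d = min(pos - intron_start + 1, intron_end - pos)
            if d <= params.essential_splice_bp:
                return Category.ESSENTIAL_SPLICE_SITE
            if d <= params.splice_intron_bp:
                return Category.SPLICE_SITE
            return Category.INTRONIC
    return Category.INTRONIC


def _spans_cds(variant: VariantCall, tx: TranscriptModel) -> bool:
    span_end = variant.pos + max(len(variant.ref), 1)
    return any(s < span_end and variant.pos < e for s, e in tx.cds)


def classify_variant(
    variant: VariantCall,
    genes: list[GeneModel],
    reference: dict[str, str],
    params: AnnotationParams | None = None,
) -> list[Consequence]:
    """Consequences of one variant, one per overlapping transcript.

    Falls back to upstream/downstream within ``flank_bp`` of a gene and
    to a single intergenic record otherwise.  Raises ``ValueError``
    when the variant's reference allele disagrees with the reference
    sequence.
    """
    params = params or AnnotationParams()
    chrom_seq = reference.get(variant.chrom)
    if chrom_seq is None:
        raise ValueError(f"variant on unknown chromosome {variant.chrom}")
    expected = chrom_seq[variant.pos : variant.pos + len(variant.ref)]
    if expected.upper() != variant.ref.upper():
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"variant says {variant.ref!r}, reference has {expected!r}"
        )
    out: list[Consequence] = []
    for gene in genes:
        if gene.chrom != variant.chrom:
            continue
        for tx in gene.transcripts:
            if tx.start <= variant.pos < tx.end:
                if _in_any(variant.pos, tx.cds) or (
                    variant.variant_class is not VariantClass.SNV
                    and _spans_cds(variant, tx)
                ):
                    category, note = _codon_consequence(tx, variant, chrom_seq)
                    out.append(
                        Consequence(category, gene.gene_id, tx.transcript_id, note)
                    )
                else:
                    category = _classify_in_transcript(tx, variant, chrom_seq, params)
                    assert category is not None
                    out.append(Consequence(category, gene.gene_id, tx.transcript_id))
            elif tx.start - params.flank_bp <= variant.pos < tx.start:
                cat = Category.UPSTREAM if tx.strand == "+" else Category.DOWNSTREAM
                out.append(Consequence(cat, gene.gene_id, tx.transcript_id))
            elif tx.end <= variant.pos < tx.end + params.flank_bp:
                cat = Category.DOWNSTREAM if tx.strand == "+" else Category.UPSTREAM
                out.append(Consequence(cat, gene.gene_id, tx.transcript_id))
    if not out:
        out.append(Consequence(Category.INTERGENIC, gene_id=""))
    return out


@dataclass(frozen=True)
class GeneLevelConsequence:
    category: Category
    gene_id: str
    affected_transcripts: int
    total_transcripts: int


def gene_level(
    consequences: list[Consequence], genes_by_id: dict[str, GeneModel] | None = None
) -> GeneLevelConsequence:
    """Collapse per-transcript consequences to the most severe category.

    ``affected_transcripts`` counts transcripts sharing that most severe
    category — e.g. a premature stop predicted only in an alternatively
    transcribed isoform shows affected < total.
    """
    if not consequences:
        raise ValueError("no consequences to collapse")
    best = min(consequences, key=lambda c: severity_rank(c.category))
    same_gene = [c for c in consequences if c.gene_id == best.gene_id]
    affected = sum(1 for c in same_gene if c.category is best.category)
    if genes_by_id and best.gene_id in genes_by_id:
        total = len(genes_by_id[best.gene_id].transcripts)
    else:
        total = len({c.transcript_id for c in same_gene if c.transcript_id})or 1
    return GeneLevelConsequence(best.category, best.gene_id, affected, total)


def summarize_consequences(
    per_strain: dict[str, list[GeneLevelConsequence]],
) -> "pd.DataFrame":
    """Category-count table: one row per category (severity order), one
    column per strain or strain-pair."""
    import pandas as pd

    data = {}
    for strain, records in per_strain.items():
        counts = {cat: 0 for cat in SEVERITY}
        for rec in records:
            counts[rec.category] += 1
        data[strain] = [counts[cat] for cat in SEVERITY]
    return pd.DataFrame(data, index=[cat.value for cat in SEVERITY])
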