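"""Per-QTL candidate reports: variant tallies inside mapped intervals.

For each quantitative-trait-locus interval, aggregates the call sets,
consequence annotation, conservation flags and strain-unique variants
into one report row (genes in the interval, genes with coding SNVs,
non-synonymous / stop / splice-site SNV counts, indel count, conserved
and unique SNV lists) plus the count of segregating SNVs — positions
where every susceptible strain carries one allele and every resistant
strain the other.  A deterministic ranking orders candidate variants by
predicted impact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from strainvar.annotate import (
    CODING_CATEGORIES,
    SPLICE_CATEGORIES,
    Category,
    ConservationTrack,
    GeneLevelConsequence,
    GeneModel,
    is_conserved,
    severity_rank,
)
from strainvar.calling import StrainCalls, VariantCall, VariantClass


@dataclass(frozen=True)
class QtlInterval:
    name: str
    chrom: str
    start: int
    end: int
    susceptible: tuple[str, ...] = ()
    resistant: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"QTL {self.name}: end must exceed start")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class QtlReport:
    interval: QtlInterval
    n_genes: int = 0
    n_genes_with_coding_snvs: int = 0
    n_ns_snvs: int = 0
    n_stop_snvs: int = 0
    n_splice_snvs: int = 0
    n_indels: int = 0
    n_segregating: int = 0
    conserved_snvs: list[tuple[VariantCall, float]] = field(default_factory=list)
    unique_snvs: list[VariantCall] = field(default_factory=list)
    variants: list[tuple[VariantCall, GeneLevelConsequence | None]] = field(
        default_factory=list
    )


def _interval_variants(
    interval: QtlInterval, strain_calls: list[StrainCalls]
) -> dict[tuple[str, int], VariantCall]:
    """Union of contrast-strain variants inside the interval."""
    contrast = set(interval.susceptible) | set(interval.resistant)
    out: dict[tuple[str, int], VariantCall] = {}
    for sc in strain_calls:
        if contrast and sc.strain not in contrast:
            continue
        for key, call in sc.calls.items():
            if interval.contains(*key):
                out.setdefault(key, call)
    return dict(sorted(out.items()))


def _count_segregating(
    interval: QtlInterval, strain_calls: list[StrainCalls], min_coverage: int = 3
) -> int:
    """Positions with strict biallelic separation of the contrast sets.

    All susceptible strains must share one allele and all resistant
    strains the other (either side may hold the reference allele);
    positions lacking coverage in any contrast strain are skipped.
    """
    by_name = {sc.strain: sc for sc in strain_calls}
    sus = [by_name[n] for n in interval.susceptible if n in by_name]
    res = [by_name[n] for n in interval.resistant if n in by_name]
    if not sus or not res:
        return 0
    keys = set()
    for sc in sus + res:
        keys.update(k for k in sc.calls if interval.contains(*k))
    n = 0
    for key in keys:
        chrom, pos = key
        if any(sc.depth_at(chrom, pos) < min_coverage for sc in sus + res):
            continue

        def allele(sc: StrainCalls) -> str | None:
            if key in sc.het_positions:
                return None
            call = sc.calls.get(key)
            return call.alt if call is not None else "REF"

        sus_alleles = {allele(sc) for sc in sus}
        res_alleles = {allele(sc) for sc in res}
        if None in sus_alleles or None in res_alleles:
            continue
        if len(sus_alleles) == 1 and len(res_alleles) == 1 and sus_alleles != res_alleles:
            n += 1
    return n


def build_report(
    interval: QtlInterval,
    strain_calls: list[StrainCalls],
    consequences: dict[tuple[str, int], GeneLevelConsequence],
    conservation: ConservationTrack | None,
    unique_snvs: set[tuple[str, int, str]],
    genes: list[GeneModel],
    conservation_threshold: float = 0.1,
) -> QtlReport:
    """Aggregate every analysis product for one QTL interval.

    ``consequences`` maps (chrom, pos) to the gene-level consequence of
    the variant there; ``unique_snvs`` is the (chrom, pos, alt) set
    from the multi-genome uniqueness comparison.
    """
    report = QtlReport(interval=interval)
    in_genes = [
        g
        for g in genes
        if g.chrom == interval.chrom
        and g.start < interval.end
        and interval.start < g.end
    ]
    report.n_genes = len(in_genes)
    variants = _interval_variants(interval, strain_calls)
    genes_with_coding: set[str] = set()
    for key, call in variants.items():
        cons = consequences.get(key)
        report.variants.append((call, cons))
        if call.variant_class is not VariantClass.SNV:
            report.n_indels += 1
            continue
        if cons is not None:
            if cons.category in CODING_CATEGORIES:
                genes_with_coding.add(cons.gene_id)
            if cons.category is Category.NON_SYNONYMOUS:
                report.n_ns_snvs += 1
            if cons.category in (Category.STOP_GAINED, Category.STOP_LOST):
                report.n_stop_snvs += 1
            if cons.category in SPLICE_CATEGORIES:
                report.n_splice_snvs += 1
        if conservation is not None and is_conserved(
            call, conservation, conservation_threshold
        ):
            report.conserved_snvs.append(
                (call, conservation.score_at(call.chrom, call.pos))
            )
        if (call.chrom, call.pos, call.alt) in unique_snvs:
            report.unique_snvs.append(call)
    report.n_genes_with_coding_snvs = len(genes_with_coding)
    report.n_segregating = _count_segregating(interval, strain_calls)
    return report


#: default ranking tiers, most interesting first
_RANK_TIERS = {
    Category.STOP_GAINED: 0,
    Category.STOP_LOST: 0,
    Category.ESSENTIAL_SPLICE_SITE: 1,
    Category.NON_SYNONYMOUS: 2,
    Category.SPLICE_SITE: 3,
    Category.UTR5: 5,
    Category.UTR3: 5,
}
_CONSERVED_NONCODING_TIER = 4
_OTHER_TIER = 6


def rank_candidates(
    report: QtlReport,
    conservation: ConservationTrack | None = None,
    conservation_threshold: float = 0.1,
) -> list[tuple[VariantCall, GeneLevelConsequence | None, int, float]]:
    """Deterministic candidate ordering for a QTL's variants.

    Premature-stop variants first, then essential splice,
    non-synonymous, splice region, conserved non-coding (by descending
    conservation score), UTR, everything else; ties break by genomic
    position.  Returns (variant, consequence, tier, score) tuples in
    rank order.
    """
    ranked = []
    conserved_keys = {(c.chrom, c.pos) for c, _s in report.conserved_snvs}
    scores = {(c.chrom, c.pos): s for c, s in report.conserved_snvs}
    for call, cons in report.variants:
        category = cons.category if cons is not None else Category.INTERGENIC
        tier = _RANK_TIERS.get(category, _OTHER_TIER)
        score = scores.get((call.chrom, call.pos), 0.0)
        if (
            tier in (_OTHER_TIER, 5)
            and category not in CODING_CATEGORIES
            and (call.chrom, call.pos) in conserved_keys
        ):
            tier = min(tier, _CONSERVED_NONCODING_TIER)
        ranked.append((call, cons, tier, score))
    ranked.sort(key=lambda t: (t[2], -t[3], t[0].chrom, t[0].pos))
    return ranked
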