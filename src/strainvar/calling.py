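"""SNV and short-indel calling from pileup summaries.

The cascade, applied per site after duplicate removal:

1. find the dominant non-reference allele (base or indel) by
   duplicate-free read count;
2. call a homozygous variant when at least ``min_calls`` supporting
   reads have base quality above ``min_call_quality`` **and** the
   supporting fraction of the duplicate-free depth is at least
   ``min_support_snv`` (0.75) for SNVs or ``min_support_indel`` (0.40)
   for indels;
3. otherwise exclude the site as residual heterozygosity when the
   supporting fraction lies in the het band (from 0.25 up to, but not
   including, the class's support threshold) — inbred genomes should be
   homozygous almost everywhere, so intermediate-support sites are
   treated as unreliable rather than as variants;
4. otherwise the site is reference (or no-data at zero depth).

A site whose supporting fraction lands exactly on the support threshold
is a call, not an exclusion.  Calls at positions where a resequenced
reference individual ("Eve") itself appears variant are blacklisted as
likely reference-assembly errors.  Calls with duplicate-free depth of at
least ``hq_min_coverage`` (8) form the high-quality set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from strainvar.config import CallingParams
from strainvar.pileup import BASES, Pileup, SiteObservation


class Zygosity(str, Enum):
    HOMOZYGOUS_VARIANT = "homozygous_variant"
    HETEROZYGOUS_EXCLUDED = "heterozygous_excluded"
    REFERENCE = "reference"
    NO_DATA = "no_data"


class VariantClass(str, Enum):
    SNV = "SNV"
    INSERTION = "insertion"
    DELETION = "deletion"


@dataclass(frozen=True)
class VariantCall:
    """A called homozygous SNV or short indel.

    ``ref``/``alt`` follow the anchored convention: for indels both
    include the anchor base at ``pos`` (insertion: alt = anchor +
    inserted sequence; deletion: ref = anchor + deleted sequence).
    """

    chrom: str
    pos: int  # 0-based anchor
    ref: str
    alt: str
    variant_class: VariantClass
    depth: int  # duplicate-free depth
    support_fraction: float
    high_quality: bool = False
    blacklisted: bool = False


@dataclass
class SiteClassification:
    zygosity: Zygosity
    call: VariantCall | None = None


@dataclass
class CallStats:
    """Per-strain exclusion and coverage bookkeeping."""

    n_calls: int = 0
    n_het_excluded: int = 0
    n_blacklist_removed: int = 0
    callable_fraction_min_calls: float = 0.0  # genome covered by >= min_calls reads
    callable_fraction_hq: float = 0.0  # genome covered by >= hq_min_coverage reads


@dataclass
class StrainCalls:
    """Calls plus the exclusion sets needed by downstream comparisons."""

    strain: str
    calls: dict[tuple[str, int], VariantCall] = field(default_factory=dict)
    het_positions: set[tuple[str, int]] = field(default_factory=set)
    depth_nodup: dict[str, np.ndarray] = field(default_factory=dict)
    stats: CallStats = field(default_factory=CallStats)

    def depth_at(self, chrom: str, pos: int) -> int:
        track = self.depth_nodup.get(chrom)
        if track is None or not 0 <= pos < len(track):
            return 0
        return int(track[pos])


def remove_duplicates(site: SiteObservation) -> SiteObservation:
    """Collapse start-position duplicate reads.

    Allele counts are already over the duplicate-free read set, so
    removal recomputes only the total depth.
    """
    return dataclasses.replace(site, depth=site.depth_nodup)


def _dominant_allele(site: SiteObservation, params: CallingParams):
    """Pick the dominant non-reference allele: (kind, allele, count).

    Bases beat an equal-count indel; base ties break alphabetically.
    Indels longer than ``indel_max_len`` are never candidates.
    """
    best_base, best_count = None, 0
    for base in BASES:
        if base == site.ref:
            continue
        c = site.counts.get(base, 0)
        if c > best_count:
            best_base, best_count = base, c
    indel_len = max(len(site.indel_seq) - 1, 0)
    indel_ok = site.indel_count > 0 and 1 <= indel_len <= params.indel_max_len
    if indel_ok and site.indel_count > best_count:
        return "indel", site.indel_seq, site.indel_count
    if best_base is not None:
        return "snv", best_base, best_count
    return None, None, 0


def classify_site(
    site: SiteObservation, params: CallingParams | None = None
) -> SiteClassification:
    """Apply the filter cascade to one duplicate-free site."""
    params = params or CallingParams()
    n = site.depth_nodup
    if n == 0:
        return SiteClassification(Zygosity.NO_DATA)
    kind, allele, _count = _dominant_allele(site, params)
    if kind is None:
        return SiteClassification(Zygosity.REFERENCE)
    k = site.hq_count_alt
    f = k / n
    min_support = params.min_support_indel if kind == "indel" else params.min_support_snv
    if k >= params.min_calls and f >= min_support:
        if kind == "indel":
            assert allele is not None
            seq = allele[1:]
            if allele.startswith("+"):
                ref, alt, vclass = site.ref, site.ref + seq, VariantClass.INSERTION
            else:
                ref, alt, vclass = site.ref + seq, site.ref, VariantClass.DELETION
        else:
            ref, alt, vclass = site.ref, str(allele), VariantClass.SNV
        call = VariantCall(
            chrom=site.chrom,
            pos=site.pos,
            ref=ref,
            alt=alt,
            variant_class=vclass,
            depth=n,
            support_fraction=f,
            high_quality=n >= params.hq_min_coverage,
        )
        return SiteClassification(Zygosity.HOMOZYGOUS_VARIANT, call)
    band_lo = params.het_band[0]
    if band_lo <= f < min_support:
        return SiteClassification(Zygosity.HETEROZYGOUS_EXCLUDED)
    return SiteClassification(Zygosity.REFERENCE)


def build_eve_blacklist(
    eve_pileup: Pileup, params: CallingParams | None = None
) -> set[tuple[str, int]]:
    """Positions where the resequenced reference individual looks variant.

    Such positions are most likely errors in the reference assembly and
    are removed from every strain's call set (SNVs and indels alike).
    """
    eve_calls = call_strain(eve_pileup, blacklist=None, params=params)
    return set(eve_calls.calls)


def call_strain(
    pileup: Pileup,
    blacklist: set[tuple[str, int]] | None = None,
    params: CallingParams | None = None,
) -> StrainCalls:
    """Run the full cascade over a strain's pileup (vectorized).

    Output is identical to applying :func:`classify_site` independently
    at every site; the vectorized path exists for genome-scale speed.
    """
    params = params or CallingParams()
    blacklist = blacklist or set()
    result = StrainCalls(strain=pileup.strain)
    covered_min = 0
    covered_hq = 0
    genome = 0
    for chrom in sorted(pileup.chroms):
        cp = pileup.chroms[chrom]
        genome += cp.length
        covered_min += int(np.count_nonzero(cp.depth_nodup >= params.min_calls))
        covered_hq += int(np.count_nonzero(cp.depth_nodup >= params.hq_min_coverage))
        result.depth_nodup[chrom] = cp.depth_nodup
        df = cp.sites
        if len(df) == 0:
            continue
        pos = df["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"pileup for {chrom} is not sorted by position")
        n = df["depth_nodup"].to_numpy(dtype=np.int64)
        counts = df[["countA", "countC", "countG", "countT"]].to_numpy(dtype=np.int64)
        refs = df["ref"].to_numpy(dtype=object)
        ref_idx = np.full(len(df), -1, dtype=np.int64)
        for i, base in enumerate(BASES):
            ref_idx[refs == base] = i
        nonref = counts.copy()
        rows_with_ref = ref_idx >= 0
        nonref[np.arange(len(df))[rows_with_ref], ref_idx[rows_with_ref]] = -1
        dom_idx = np.argmax(nonref, axis=1)  # first max -> alphabetical tie-break
        dom_count = nonref[np.arange(len(df)), dom_idx]
        dom_count = np.maximum(dom_count, 0)

        indel_count = df["count_indel_allele"].to_numpy(dtype=np.int64)
        indel_seqs = df["indel_seq"].to_numpy(dtype=object)
        indel_lens = np.array(
            [max(len(s) - 1, 0) for s in indel_seqs], dtype=np.int64
        )
        indel_ok = (
            (indel_count > 0)
            & (indel_lens >= 1)
            & (indel_lens <= params.indel_max_len)
        )
        use_indel = indel_ok & (indel_count > dom_count)
        has_candidate = (dom_count > 0) | use_indel

        k = df["hq_count_alt"].to_numpy(dtype=np.int64)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(n > 0, k / np.maximum(n, 1), 0.0)
        min_sup = np.where(use_indel, params.min_support_indel, params.min_support_snv)
        called = (
            (n > 0) & has_candidate & (k >= params.min_calls) & (f >= min_sup)
        )
        het = (
            (n > 0)
            & has_candidate
            & ~called
            & (f >= params.het_band[0])
            & (f < min_sup)
        )

        for i in np.flatnonzero(het):
            result.het_positions.add((chrom, int(pos[i])))
        result.stats.n_het_excluded += int(np.count_nonzero(het))

        for i in np.flatnonzero(called):
            p = int(pos[i])
            if (chrom, p) in blacklist:
                result.stats.n_blacklist_removed += 1
                continue
            ref = str(refs[i])
            if use_indel[i]:
                seq = str(indel_seqs[i])[1:]
                if str(indel_seqs[i]).startswith("+"):
                    call_ref, alt, vclass = ref, ref + seq, VariantClass.INSERTION
                else:
                    call_ref, alt, vclass = ref + seq, ref, VariantClass.DELETION
            else:
                call_ref, alt, vclass = ref, BASES[dom_idx[i]], VariantClass.SNV
            result.calls[(chrom, p)] = VariantCall(
                chrom=chrom,
                pos=p,
                ref=call_ref,
                alt=alt,
                variant_class=vclass,
                depth=int(n[i]),
                support_fraction=float(f[i]),
                high_quality=bool(n[i] >= params.hq_min_coverage),
            )
    result.stats.n_calls = len(result.calls)
    if genome > 0:
        result.stats.callable_fraction_min_calls = covered_min / genome
        result.stats.callable_fraction_hq = covered_hq / genome
    return result


def estimate_sensitivity(
    calls: StrainCalls, panel: "pd.DataFrame", strain: str
) -> float:
    """Fraction of panel markers differing from reference that were called.

    ``panel`` is a genotype-panel table with columns ``chrom``, ``pos``
    (0-based), ``ref`` and one allele column per strain.  Over markers
    where the panel records a non-reference allele for ``strain``, the
    sensitivity is the fraction recovered in the call set with the same
    alternate allele.
    """
    if strain not in panel.columns:
        raise KeyError(f"strain {strain!r} not in panel")
    differing = panel[panel[strain] != panel["ref"]]
    if len(differing) == 0:
        raise ValueError("no panel markers differ from the reference")
    hit = 0
    for chrom, pos, allele in zip(
        differing["chrom"], differing["pos"], differing[strain]
    ):
        call = calls.calls.get((str(chrom), int(pos)))
        if call is not None and call.alt == allele:
            hit += 1
    return hit / len(differing)
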