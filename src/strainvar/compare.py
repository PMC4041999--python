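"""Multi-strain SNV sharing, unique variants and sub-strain regions.

Three related analyses on per-strain call sets against a common
reference:

* a Venn-style sharing partition over all strains — each analyzed SNV
  position is assigned to the subset of strains carrying a
  non-reference allele there, after excluding positions where any
  strain is heterozygous-excluded or under-covered;
* detection of differentiating regions between two closely related
  sub-strains, as windows of elevated genotype-difference density,
  followed by ancestry matching of each region against a genotype
  panel;
* identification of variants unique to a target strain set relative to
  a panel of other genomes, with coverage-aware handling of positions
  the non-target genomes cannot resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strainvar.calling import StrainCalls, VariantClass
from strainvar.config import ComparisonParams


@dataclass
class SharingPartition:
    """Venn partition of SNV positions across strains."""

    counts: dict[frozenset, int]
    fractions: dict[frozenset, float]
    analyzed_positions: int
    excluded_positions: int

    @property
    def total_positions(self) -> int:
        return self.analyzed_positions + self.excluded_positions


def partition_sharing(
    strain_calls: list[StrainCalls],
    min_coverage: int = 3,
) -> SharingPartition:
    """Assign each SNV position to the subset of strains that carry it.

    Positions where at least one strain is heterozygous-excluded or has
    duplicate-free coverage below ``min_coverage`` are excluded from
    the partition and tallied separately; fractions are over the
    analyzed positions and sum to 1.
    """
    if len(strain_calls) < 2:
        raise ValueError("need at least two strains to partition sharing")
    positions: set[tuple[str, int]] = set()
    for sc in strain_calls:
        positions.update(
            key
            for key, call in sc.calls.items()
            if call.variant_class is VariantClass.SNV
        )
        positions.update(sc.het_positions)
    counts: dict[frozenset, int] = {}
    excluded = 0
    for key in positions:
        chrom, pos = key
        bad = False
        for sc in strain_calls:
            if key in sc.het_positions or sc.depth_at(chrom, pos) < min_coverage:
                bad = True
                break
        if bad:
            excluded += 1
            continue
        subset = frozenset(
            sc.strain
            for sc in strain_calls
            if key in sc.calls and sc.calls[key].variant_class is VariantClass.SNV
        )
        if not subset:
            excluded += 1  # all carriers vanished: nothing to assign
            continue
        counts[subset] = counts.get(subset, 0) + 1
    analyzed = sum(counts.values())
    fractions = {k: v / analyzed for k, v in counts.items()} if analyzed else {}
    return SharingPartition(
        counts=counts,
        fractions=fractions,
        analyzed_positions=analyzed,
        excluded_positions=excluded,
    )


def pairwise_sharing(
    calls_a: StrainCalls, calls_b: StrainCalls, hq_only: bool = False
) -> float:
    """Fraction of A's variants present in B with the same alternate
    allele (optionally restricted to A's high-quality calls)."""
    items = [
        (key, call)
        for key, call in calls_a.calls.items()
        if not hq_only or call.high_quality
    ]
    if not items:
        raise ValueError("strain A has no (qualifying) calls")
    shared = sum(
        1
        for key, call in items
        if key in calls_b.calls and calls_b.calls[key].alt == call.alt
    )
    return shared / len(items)


@dataclass
class DifferentiatingRegion:
    chrom: str
    start: int
    end: int
    snv_count: int
    density_per_mbp: float
    matched_ancestors: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


def _genotype_differs(calls_a: StrainCalls, calls_b: StrainCalls, key) -> bool:
    a = calls_a.calls.get(key)
    b = calls_b.calls.get(key)
    if a is None and b is None:
        return False
    if a is None or b is None:
        return True
    return a.alt != b.alt


def detect_differentiating_regions(
    calls_a: StrainCalls,
    calls_b: StrainCalls,
    params: ComparisonParams | None = None,
) -> list[DifferentiatingRegion]:
    """Windows of elevated genotype-difference density between two
    sub-strains.

    Only positions covered by at least ``region_min_coverage`` reads in
    both strains count.  Fixed windows of ``region_window`` bp whose
    count of differing positions exceeds the density threshold merge
    into regions, bridging gaps of up to ``region_merge_gap``
    below-threshold windows.
    """
    params = params or ComparisonParams()
    window = params.region_window
    min_count = params.region_density_per_mbp * window / 1e6
    diff_positions: dict[str, list[int]] = {}
    keys = set(calls_a.calls) | set(calls_b.calls)
    for key in keys:
        chrom, pos = key
        if (
            calls_a.depth_at(chrom, pos) >= params.region_min_coverage
            and calls_b.depth_at(chrom, pos) >= params.region_min_coverage
            and _genotype_differs(calls_a, calls_b, key)
        ):
            diff_positions.setdefault(chrom, []).append(pos)

    regions: list[DifferentiatingRegion] = []
    chrom_lengths = {
        chrom: len(track) for chrom, track in calls_a.depth_nodup.items()
    }
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        n_windows = (length + window - 1) // window
        counts = np.zeros(n_windows, dtype=np.int64)
        for pos in diff_positions.get(chrom, []):
            counts[pos // window] += 1
        above = counts >= min_count
        i = 0
        while i < n_windows:
            if not above[i]:
                i += 1
                continue
            j = i
            last_above = i
            while j + 1 < n_windows:
                nxt = j + 1
                if above[nxt]:
                    j = nxt
                    last_above = nxt
                    continue
                # bridge a short gap only if another above-window follows
                gap_end = min(nxt + params.region_merge_gap, n_windows)
                bridged = next(
                    (g for g in range(nxt, gap_end) if above[g]), None
                )
                if bridged is None:
                    break
                j = bridged
                last_above = bridged
            start = i * window
            end = min((last_above + 1) * window, length)
            count = int(
                sum(1 for p in diff_positions.get(chrom, []) if start <= p < end)
            )
            regions.append(
                DifferentiatingRegion(
                    chrom=chrom,
                    start=start,
                    end=end,
                    snv_count=count,
                    density_per_mbp=count / (end - start) * 1e6,
                )
            )
            i = last_above + 1
    return regions


def match_ancestry(
    region: DifferentiatingRegion,
    calls_a: StrainCalls,
    calls_b: StrainCalls,
    panel: pd.DataFrame,
    params: ComparisonParams | None = None,
) -> dict[str, list[tuple[str, float]]]:
    """Identity of each sub-strain to each panel strain over in-region
    markers; reports every panel strain within the tie margin of the
    best identity.  Reference-allele matches are informative: identity
    is computed over all markers in the region, not only variant sites.
    """
    params = params or ComparisonParams()
    in_region = panel[
        (panel["chrom"] == region.chrom)
        & (panel["pos"] >= region.start)
        & (panel["pos"] < region.end)
    ]
    if len(in_region) == 0:
        raise ValueError("no panel markers inside the region")
    meta_cols = {"chrom", "pos", "ref"}
    sub_strains = {calls_a.strain: calls_a, calls_b.strain: calls_b}
    candidate_cols = [
        c for c in panel.columns if c not in meta_cols and c not in sub_strains
    ]
    result: dict[str, list[tuple[str, float]]] = {}
    for name, sc in sub_strains.items():
        own = []
        for chrom, pos, ref in zip(
            in_region["chrom"], in_region["pos"], in_region["ref"]
        ):
            call = sc.calls.get((str(chrom), int(pos)))
            own.append(call.alt if call is not None else ref)
        own_arr = np.array(own, dtype=object)
        identities = {
            cand: float(np.mean(own_arr == in_region[cand].to_numpy(dtype=object)))
            for cand in candidate_cols
        }
        if not identities:
            result[name] = []
            continue
        best = max(identities.values())
        result[name] = sorted(
            (
                (cand, ident)
                for cand, ident in identities.items()
                if ident >= best - params.ancestry_tie_margin
            ),
            key=lambda t: (-t[1], t[0]),
        )
    region.matched_ancestors = result
    return result


@dataclass
class UniqueSnvResult:
    unique: set[tuple[str, int, str]]  # (chrom, pos, alt)
    unresolved: set[tuple[str, int, str]]  # lacking coverage in a non-target


def find_unique_snvs(
    target_names: list[str],
    all_calls: list[StrainCalls],
    min_coverage: int = 3,
) -> UniqueSnvResult:
    """Variants carried by every target strain and absent from every
    adequately covered non-target genome.

    Positions a non-target genome cannot resolve (coverage below
    ``min_coverage``) are reported separately as unresolved rather than
    counted as unique.
    """
    by_name = {sc.strain: sc for sc in all_calls}
    targets = [by_name[n] for n in target_names]
    others = [sc for sc in all_calls if sc.strain not in target_names]
    if not others:
        raise ValueError("need at least one non-target genome")
    first = targets[0]
    unique: set[tuple[str, int, str]] = set()
    unresolved: set[tuple[str, int, str]] = set()
    for key, call in first.calls.items():
        if not all(
            key in t.calls and t.calls[key].alt == call.alt for t in targets[1:]
        ):
            continue
        chrom, pos = key
        present_elsewhere = any(
            key in o.calls and o.calls[key].alt == call.alt for o in others
        )
        if present_elsewhere:
            continue
        covered_everywhere = all(
            o.depth_at(chrom, pos) >= min_coverage for o in others
        )
        record = (chrom, pos, call.alt)
        if covered_everywhere:
            unique.add(record)
        else:
            unresolved.add(record)
    return UniqueSnvResult(unique=unique, unresolved=unresolved)
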