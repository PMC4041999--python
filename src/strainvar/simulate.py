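"""Synthetic genomes, truth sets and noisy pileups with known ground truth.

The generator emulates the data a resequencing study of inbred rat-like
strains produces after alignment: near-fully homozygous genomes that
differ from a reference by SNVs, short indels (< 10 bp) and copy-number
changes; Poisson-distributed per-site coverage around a ~20X median;
per-base miscalls; start-position duplicate reads; a residue of
unfixed heterozygous loci; and — for sub-strain pairs — a region-mosaic
structure where the two genomes are identical outside a stated set of
ancestry segments and diverge independently inside them.

Everything is driven by one integer seed and is byte-deterministic.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from strainvar.config import ConfigurationError, SimulationConfig
from strainvar.pileup import BASES, ChromPileup, Pileup, empty_sites

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)

#: probability a simulated base call has quality 30 (the remainder have
#: quality 5, i.e. below the "> 10" calling cut)
HIGH_QUALITY_PROB = 0.99


@dataclass(frozen=True)
class MosaicSegment:
    """An ancestry segment inside which a sub-strain pair diverges."""

    chrom: str
    start: int
    end: int
    donor_a: str = ""
    donor_b: str = ""

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class StrainTruth:
    """Ground-truth variants of one simulated strain.

    ``snvs``: set of (chrom, pos, ref, alt); ``indels``: set of
    (chrom, pos, ref_seq, alt_seq) with the anchored convention;
    ``het_sites``: residual heterozygous loci (chrom, pos, ref, alt);
    ``cnvs``: (chrom, start, end, copy_number) with copy in {0, 2};
    ``ancestry``: (chrom, start, end, donor label).
    """

    name: str
    snvs: set[tuple[str, int, str, str]] = field(default_factory=set)
    indels: set[tuple[str, int, str, str]] = field(default_factory=set)
    het_sites: set[tuple[str, int, str, str]] = field(default_factory=set)
    cnvs: list[tuple[str, int, int, int]] = field(default_factory=list)
    ancestry: list[tuple[str, int, int, str]] = field(default_factory=list)

    def snv_positions(self) -> set[tuple[str, int]]:
        return {(c, p) for c, p, _, _ in self.snvs}

    def variant_positions(self) -> set[tuple[str, int]]:
        return self.snv_positions() | {(c, p) for c, p, _, _ in self.indels}


def _rng_for(config: SimulationConfig, *tags: str) -> np.random.Generator:
    """Deterministic child generator keyed on the config seed and tags."""
    entropy = [int(config.seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(t.encode()) for t in tags)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def simulate_reference(config: SimulationConfig) -> dict[str, str]:
    """Uniform-random reference sequence per chromosome."""
    rng = _rng_for(config, "reference")
    ref: dict[str, str] = {}
    for chrom, length in config.chromosome_lengths.items():
        idx = rng.integers(0, 4, size=int(length))
        ref[chrom] = _BASE_ARR[idx].tobytes().decode()
    return ref


def _draw_positions(
    rng: np.random.Generator, length: int, rate: float, forbidden: set[int]
) -> np.ndarray:
    n = rng.binomial(length, rate)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    pos = rng.choice(length, size=n, replace=False)
    pos = np.array(sorted(int(p) for p in pos if int(p) not in forbidden))
    return pos


def _other_base(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in BASES if b != ref_base]
    return choices[int(rng.integers(0, 3))]


def _simulate_one_strain(
    name: str, reference: dict[str, str], config: SimulationConfig, tag: str
) -> StrainTruth:
    rng = _rng_for(config, "strain", tag)
    truth = StrainTruth(name=name)
    for chrom, seq in reference.items():
        length = len(seq)
        taken: set[int] = set()
        # SNVs
        for p in _draw_positions(rng, length, config.snv_rate, taken):
            ref_base = seq[p]
            truth.snvs.add((chrom, int(p), ref_base, _other_base(rng, ref_base)))
            taken.add(int(p))
        # short indels, anchored at the preceding base
        for p in _draw_positions(rng, length, config.indel_rate, taken):
            p = int(p)
            ilen = int(rng.integers(1, config.indel_max_len + 1))
            anchor = seq[p]
            if rng.random() < 0.5 and p + 1 + ilen <= length:
                span = set(range(p, p + 1 + ilen))
                if span & taken:
                    continue
                truth.indels.add((chrom, p, seq[p : p + 1 + ilen], anchor))
                taken |= span
            else:
                ins = "".join(
                    BASES[int(b)] for b in rng.integers(0, 4, size=ilen)
                )
                truth.indels.add((chrom, p, anchor, anchor + ins))
                taken.add(p)
        # residual heterozygous loci
        for p in _draw_positions(rng, length, config.het_site_fraction, taken):
            ref_base = seq[p]
            truth.het_sites.add(
                (chrom, int(p), ref_base, _other_base(rng, ref_base))
            )
            taken.add(int(p))
    return truth


def _strip_cnv_deletions(truth: StrainTruth) -> None:
    """Drop truth variants inside homozygous-deletion segments."""
    zero = [(c, s, e) for c, s, e, copy in truth.cnvs if copy == 0]
    if not zero:
        return

    def gone(chrom: str, pos: int) -> bool:
        return any(c == chrom and s <= pos < e for c, s, e in zero)

    truth.snvs = {v for v in truth.snvs if not gone(v[0], v[1])}
    truth.indels = {v for v in truth.indels if not gone(v[0], v[1])}
    truth.het_sites = {v for v in truth.het_sites if not gone(v[0], v[1])}


def simulate_strains(
    config: SimulationConfig,
    n_strains: int,
    mosaic_pairs: (
        list[tuple[str, str, list[MosaicSegment]]] | None
    ) = None,
    cnvs: dict[str, list[tuple[str, int, int, int]]] | None = None,
    strain_names: list[str] | None = None,
) -> tuple[dict[str, str], list[StrainTruth]]:
    """Generate a reference and per-strain truth sets.

    ``mosaic_pairs`` is a list of ``(name_a, name_b, segments)``: strain
    *b* is rebuilt to carry exactly *a*'s variants outside the segments
    while keeping its own, independently drawn, variants inside them.
    ``cnvs`` assigns copy-number events (copy 0 or 2) per strain; truth
    variants falling inside a homozygous deletion are removed, since no
    read can observe them.
    """
    if n_strains < 1:
        raise ConfigurationError("n_strains must be >= 1")
    names = strain_names or [f"S{i + 1}" for i in range(n_strains)]
    if len(names) != n_strains:
        raise ConfigurationError("strain_names length must equal n_strains")
    mosaic_pairs = mosaic_pairs or []
    for a, b, _segments in mosaic_pairs:
        if a not in names or b not in names:
            raise ConfigurationError(f"mosaic pair ({a}, {b}) names unknown strains")

    reference = simulate_reference(config)
    truths = {
        name: _simulate_one_strain(name, reference, config, name) for name in names
    }

    for a, b, segments in mosaic_pairs:
        ta, tb = truths[a], truths[b]

        def inside(chrom: str, pos: int) -> bool:
            return any(seg.contains(chrom, pos) for seg in segments)

        for attr in ("snvs", "indels", "het_sites"):
            own = {v for v in getattr(tb, attr) if inside(v[0], v[1])}
            shared = {v for v in getattr(ta, attr) if not inside(v[0], v[1])}
            setattr(tb, attr, own | shared)
        ta.ancestry = [(s.chrom, s.start, s.end, s.donor_a) for s in segments]
        tb.ancestry = [(s.chrom, s.start, s.end, s.donor_b) for s in segments]

    if cnvs:
        for name, events in cnvs.items():
            if name not in truths:
                raise ConfigurationError(f"CNVs given for unknown strain {name}")
            events = sorted(events)
            for (c1, s1, e1, _k1), (c2, s2, e2, _k2) in zip(events, events[1:]):
                if c1 == c2 and s2 < e1:
                    raise ConfigurationError(
                        f"overlapping CNV intervals for strain {name}"
                    )
            truths[name].cnvs = list(events)
            _strip_cnv_deletions(truths[name])

    for truth in truths.values():
        seen: set[tuple[str, int]] = set()
        for c, p, _r, _a in truth.snvs | truth.indels | truth.het_sites:
            if (c, p) in seen:
                raise AssertionError(f"duplicate truth position {c}:{p}")
            seen.add((c, p))
    return reference, [truths[n] for n in names]


def _copy_multiplier(
    truth: StrainTruth, chrom: str, length: int
) -> np.ndarray:
    mult = np.ones(length, dtype=np.float64)
    for c, s, e, copy in truth.cnvs:
        if c == chrom:
            mult[s:e] = 0.0 if copy == 0 else copy / 1.0
    return mult


def _split_counts(
    rng: np.random.Generator, total: np.ndarray, n_ways: int
) -> list[np.ndarray]:
    """Split per-site totals uniformly among ``n_ways`` categories."""
    parts: list[np.ndarray] = []
    remaining = total.astype(np.int64)
    for i in range(n_ways - 1):
        p = 1.0 / (n_ways - i)
        drawn = rng.binomial(remaining, p)
        parts.append(drawn)
        remaining = remaining - drawn
    parts.append(remaining)
    return parts


def simulate_pileup(
    reference: dict[str, str],
    truth: StrainTruth,
    config: SimulationConfig,
) -> tuple[Pileup, dict[str, np.ndarray]]:
    """Simulate a per-site pileup and a unique-read-start track.

    Per site the duplicate-free depth is Poisson(median_coverage x
    local copy multiplier: 0 inside homozygous deletions, 2 inside
    duplications); each read shows the strain's true allele except for
    per-base miscalls to a uniform other base; start-position duplicate
    reads inflate the raw depth column only.  Base qualities follow a
    two-point model (quality 30 with probability 0.99, else quality 5),
    so ``hq_count_alt`` counts the supporting reads passing the "> 10"
    quality cut.  The start track counts unique read starts per
    position at rate median_coverage / read_length (scaled by copy
    number), which is what the CNV detector consumes.
    """
    rng = _rng_for(config, "pileup", truth.name)
    chroms: dict[str, ChromPileup] = {}
    starts: dict[str, np.ndarray] = {}
    snv_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    het_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    indel_by_chrom: dict[str, list[tuple[int, str, str]]] = {}
    for c, p, r, a in truth.snvs:
        snv_by_chrom.setdefault(c, []).append((p, r, a))
    for c, p, r, a in truth.het_sites:
        het_by_chrom.setdefault(c, []).append((p, r, a))
    for c, p, r, a in truth.indels:
        indel_by_chrom.setdefault(c, []).append((p, r, a))

    for chrom, seq in reference.items():
        length = len(seq)
        for p, _r, _a in (
            snv_by_chrom.get(chrom, [])
            + het_by_chrom.get(chrom, [])
            + indel_by_chrom.get(chrom, [])
        ):
            if not 0 <= p < length:
                raise ConfigurationError(
                    f"truth position {chrom}:{p} outside the reference"
                )
        mult = _copy_multiplier(truth, chrom, length)
        depth_nodup = rng.poisson(config.median_coverage * mult).astype(np.int32)
        dups = rng.binomial(depth_nodup, config.duplicate_fraction).astype(np.int32)
        depth = depth_nodup + dups

        # background miscalls at every site
        err = rng.binomial(depth_nodup, config.per_base_error).astype(np.int32)

        ref_codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref_idx = np.searchsorted(_BASE_ARR, ref_codes)  # ACGT are sorted

        special = {
            p
            for p, _r, _a in (
                snv_by_chrom.get(chrom, [])
                + het_by_chrom.get(chrom, [])
                + indel_by_chrom.get(chrom, [])
            )
        }
        err_pos = np.flatnonzero(err)
        sparse_pos = np.union1d(
            err_pos, np.fromiter(special, dtype=np.int64, count=len(special))
        ).astype(np.int64)
        m = len(sparse_pos)
        counts = np.zeros((m, 4), dtype=np.int64)
        indel_count = np.zeros(m, dtype=np.int64)
        indel_seq = np.full(m, "", dtype=object)
        pos_index = {int(p): i for i, p in enumerate(sparse_pos)}

        u = depth_nodup[sparse_pos].astype(np.int64)
        site_err = err[sparse_pos].astype(np.int64)
        site_ref = ref_idx[sparse_pos]

        # default (reference-true) sites: u - err reads show ref, the err
        # reads split uniformly among the three other bases
        err_parts = _split_counts(rng, site_err, 3)
        if m:
            counts[np.arange(m), site_ref] = u - site_err
            for b_ref in range(4):
                mask = site_ref == b_ref
                if not mask.any():
                    continue
                others = [b for b in range(4) if b != b_ref]
                for j, b in enumerate(others):
                    counts[mask, b] = err_parts[j][mask]

        def overwrite(p: int, ref_b: str, true_alleles: list[tuple[str, float]]):
            """Redo a site's counts from its true allele mix."""
            i = pos_index[p]
            n = int(depth_nodup[p])
            counts[i, :] = 0
            indel_count[i] = 0
            remaining = n
            for allele, frac in true_alleles[:-1]:
                k = int(rng.binomial(remaining, frac))
                _deposit(i, allele, k)
                remaining -= k
            _deposit(i, true_alleles[-1][0], remaining)

        def _deposit(i: int, allele: str, k: int) -> None:
            if k == 0:
                return
            miscalled = int(rng.binomial(k, config.per_base_error))
            good = k - miscalled
            if allele.startswith(("+", "-")):
                indel_count[i] += good
                indel_seq[i] = allele
                # miscalled indel-supporting reads read as reference base
                counts[i, site_ref[i]] += miscalled
            else:
                b = BASES.index(allele)
                counts[i, b] += good
                spill = [x for x in range(4) if x != b]
                for j in range(miscalled):
                    counts[i, spill[int(rng.integers(0, 3))]] += 1

        for p, r, a in snv_by_chrom.get(chrom, []):
            overwrite(p, r, [(a, 1.0)])
        for p, r, a in het_by_chrom.get(chrom, []):
            overwrite(p, r, [(a, 0.5), (r, 1.0)])
        for p, r, a in indel_by_chrom.get(chrom, []):
            allele = ("+" + a[len(r) :]) if len(a) > len(r) else ("-" + r[len(a) :])
            overwrite(p, r, [(allele, 1.0)])

        # dominant non-reference allele and its quality-passing support
        nonref = counts.copy()
        nonref[np.arange(m), site_ref] = -1
        dom_idx = np.argmax(nonref, axis=1)
        dom_count = np.maximum(nonref[np.arange(m), dom_idx], 0)
        dom_count = np.where(indel_count > dom_count, indel_count, dom_count)
        hq = rng.binomial(dom_count, HIGH_QUALITY_PROB).astype(np.int64)

        sites = pd.DataFrame(
            {
                "pos": sparse_pos,
                "ref": [BASES[b] for b in site_ref],
                "depth": depth[sparse_pos].astype(np.int32),
                "depth_nodup": depth_nodup[sparse_pos].astype(np.int32),
                "countA": counts[:, 0].astype(np.int32),
                "countC": counts[:, 1].astype(np.int32),
                "countG": counts[:, 2].astype(np.int32),
                "countT": counts[:, 3].astype(np.int32),
                "count_indel_allele": indel_count.astype(np.int32),
                "indel_seq": indel_seq,
                "hq_count_alt": hq.astype(np.int32),
            }
        )
        if m == 0:
            sites = empty_sites()
        chroms[chrom] = ChromPileup(
            length=length, depth=depth, depth_nodup=depth_nodup, sites=sites
        )
        start_rate = config.median_coverage / config.read_length
        starts[chrom] = rng.poisson(start_rate * mult).astype(np.int32)

    return Pileup(strain=truth.name, chroms=chroms), starts


def simulate_genotype_panel(
    truths: list[StrainTruth],
    n_markers: int,
    reference: dict[str, str],
    config: SimulationConfig,
    ancestor_match_outside: float = 0.5,
) -> pd.DataFrame:
    """A marker panel typed across strains, plus synthetic ancestors.

    Markers are drawn from the union of truth SNV positions topped up
    with reference-identical positions.  Each strain's allele comes from
    its truth set.  For every ancestry-segment donor label found in the
    truths, an ancestor column is added that matches its strain exactly
    inside the donated segments and with probability
    ``ancestor_match_outside`` elsewhere.
    """
    if n_markers < 1:
        raise ConfigurationError("n_markers must be >= 1")
    rng = _rng_for(config, "panel")
    variant_positions = sorted(set().union(*[t.snv_positions() for t in truths]))
    n_var = min(len(variant_positions), n_markers)
    chosen = [
        variant_positions[i]
        for i in sorted(
            rng.choice(len(variant_positions), size=n_var, replace=False)
        )
    ] if n_var else []
    used = set(chosen)
    # top up with reference-identical positions
    chrom_names = sorted(reference)
    while len(chosen) < n_markers:
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        p = int(rng.integers(0, len(reference[chrom])))
        if (chrom, p) in used:
            continue
        used.add((chrom, p))
        chosen.append((chrom, p))
    chosen = sorted(chosen)

    snv_maps = {
        t.name: {(c, p): a for c, p, _r, a in t.snvs} for t in truths
    }
    rows: dict[str, list] = {
        "chrom": [],
        "pos": [],
        "ref": [],
        **{t.name: [] for t in truths},
    }
    donors: dict[str, tuple[str, list[tuple[str, int, int]]]] = {}
    for t in truths:
        for chrom, s, e, label in t.ancestry:
            if label:
                donors.setdefault(label, (t.name, []))[1].append((chrom, s, e))
    for label in donors:
        rows[label] = []

    for chrom, p in chosen:
        ref_base = reference[chrom][p]
        rows["chrom"].append(chrom)
        rows["pos"].append(p)
        rows["ref"].append(ref_base)
        for t in truths:
            rows[t.name].append(snv_maps[t.name].get((chrom, p), ref_base))
        for label, (strain, segments) in donors.items():
            strain_allele = snv_maps[strain].get((chrom, p), ref_base)
            inside = any(c == chrom and s <= p < e for c, s, e in segments)
            if inside or rng.random() < ancestor_match_outside:
                rows[label].append(strain_allele)
            else:
                rows[label].append(
                    ref_base if strain_allele != ref_base else _other_base(rng, ref_base)
                )
    return pd.DataFrame(rows)


def simulate_genes(
    reference: dict[str, str],
    config: SimulationConfig,
    n_genes: int = 50,
    min_gap: int = 2000,
) -> list["GeneModel"]:
    """Protein-coding gene models scattered over the reference.

    Each gene has 2-5 exons with UTRs at both ends, a CDS whose length
    is divisible by 3, and — half the time — a second transcript
    skipping one internal exon (its CDS re-trimmed to a multiple of 3).
    Genes are non-overlapping with at least ``min_gap`` bp between them.
    """
    from strainvar.annotate import GeneModel, TranscriptModel

    rng = _rng_for(config, "genes")
    genes: list[GeneModel] = []
    chrom_names = sorted(reference)
    per_chrom = max(1, n_genes // len(chrom_names))
    gene_no = 0
    for chrom in chrom_names:
        length = len(reference[chrom])
        cursor = int(rng.integers(min_gap, 2 * min_gap))
        for _ in range(per_chrom):
            if gene_no >= n_genes:
                break
            k = int(rng.integers(2, 6))
            exon_lens = rng.integers(90, 241, size=k)
            intron_lens = rng.integers(60, 401, size=k - 1)
            span = int(exon_lens.sum() + intron_lens.sum())
            if cursor + span + min_gap >= length:
                break
            exons = []
            s = cursor
            for i in range(k):
                exons.append((s, s + int(exon_lens[i])))
                s += int(exon_lens[i])
                if i < k - 1:
                    s += int(intron_lens[i])
            utr5 = int(rng.integers(10, min(41, exon_lens[0] - 10)))
            utr3 = int(rng.integers(10, min(41, exon_lens[-1] - 10)))
            total_exonic = int(exon_lens.sum())
            cds_len = total_exonic - utr5 - utr3
            utr3 += cds_len % 3
            cds = _trim_to_cds(exons, utr5, utr3)
            strand = "+" if rng.random() < 0.5 else "-"
            gene_no += 1
            gid = f"G{gene_no:05d}"
            transcripts = [
                TranscriptModel(f"{gid}.t1", gid, chrom, strand, exons, cds)
            ]
            if k >= 3 and rng.random() < 0.5:
                skip = int(rng.integers(1, k - 1))
                alt_exons = [ex for i, ex in enumerate(exons) if i != skip]
                alt_cds = [
                    (max(s0, cs), min(e0, ce))
                    for s0, e0 in alt_exons
                    for cs, ce in cds
                    if max(s0, cs) < min(e0, ce)
                ]
                alt_cds = _retrim_mod3(alt_cds, strand)
                if alt_cds:
                    transcripts.append(
                        TranscriptModel(
                            f"{gid}.t2", gid, chrom, strand, alt_exons, alt_cds
                        )
                    )
            genes.append(GeneModel(gid, chrom, strand, transcripts))
            cursor += span + min_gap + int(rng.integers(0, min_gap))
    return genes


def _trim_to_cds(
    exons: list[tuple[int, int]], utr5: int, utr3: int
) -> list[tuple[int, int]]:
    """CDS intervals after removing utr5 bases from the exon chain's
    left end and utr3 from its right end (genomic orientation)."""
    cds: list[tuple[int, int]] = []
    skip = utr5
    for s, e in exons:
        seg_len = e - s
        if skip >= seg_len:
            skip -= seg_len
            continue
        cds.append((s + skip, e))
        skip = 0
    trim = utr3
    while trim > 0 and cds:
        s, e = cds[-1]
        if trim >= e - s:
            trim -= e - s
            cds.pop()
        else:
            cds[-1] = (s, e - trim)
            trim = 0
    return cds


def _retrim_mod3(cds: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    """Trim a CDS at its translational 3' end to a multiple of 3."""
    cds = [(s, e) for s, e in cds if e > s]
    excess = sum(e - s for s, e in cds) % 3
    while excess and cds:
        if strand == "+":
            s, e = cds[-1]
            cut = min(excess, e - s)
            cds[-1] = (s, e - cut)
            if cds[-1][0] >= cds[-1][1]:
                cds.pop()
        else:
            s, e = cds[0]
            cut = min(excess, e - s)
            cds[0] = (s + cut, e)
            if cds[0][0] >= cds[0][1]:
                cds.pop(0)
        excess -= cut
    return cds


def simulate_conservation(
    reference: dict[str, str],
    config: SimulationConfig,
    block_fraction: float = 0.05,
) -> "ConservationTrack":
    """Piecewise-constant conservation: random blocks (100-1000 bp) with
    scores uniform in [0, 1]; everything else scores 0."""
    from strainvar.annotate import ConservationTrack

    rng = _rng_for(config, "conservation")
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, seq in reference.items():
        length = len(seq)
        rows: list[tuple[int, int, float]] = []
        covered = 0
        cursor = 0
        target = block_fraction * length
        while covered < target:
            gap = int(rng.integers(200, 4000))
            block = int(rng.integers(100, 1001))
            start = cursor + gap
            end = start + block
            if end >= length:
                break
            score = round(float(rng.uniform(0.0, 1.0)), 3)
            rows.append((start, end, score))
            covered += block
            cursor = end
        intervals[chrom] = rows
    return ConservationTrack(intervals)


def assign_expression_categories(
    gene_ids: list[str],
    flagged: np.ndarray,
    odds_ratio: float,
    n_de: tuple[int, int, int, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign fold-change tiers so flagged genes enter the DE set with
    the stated odds ratio (weighted sampling without replacement via
    Gumbel top-k).

    ``n_de`` lists cumulative tier sizes (strongest first) plus the
    not-DE count, e.g. (88, 214, 520, 14140): 88 genes exceed the top
    fold-change threshold, 214 the middle one, 520 the lowest, and
    14140 show no differential expression.
    """
    if odds_ratio < 1:
        raise ConfigurationError("odds_ratio must be >= 1")
    n1, n2, n3, n_null = n_de
    if not n1 <= n2 <= n3:
        raise ConfigurationError("tier sizes must be cumulative (non-decreasing)")
    total = n3 + n_null
    if total > len(gene_ids):
        raise ConfigurationError(
            f"category sizes need {total} genes, only {len(gene_ids)} simulated"
        )
    idx = np.arange(len(gene_ids))
    if total < len(gene_ids):
        idx = rng.choice(len(gene_ids), size=total, replace=False)
    flags = np.asarray(flagged, dtype=bool)[idx]
    weights = np.where(flags, float(odds_ratio), 1.0)
    keys = np.log(weights) + rng.gumbel(size=total)
    order = np.argsort(-keys)
    de_local = order[:n3]
    tiers = rng.permutation(n3)
    fold = np.full(total, 1.0)
    fold[de_local[tiers < n1]] = 2.5
    fold[de_local[(tiers >= n1) & (tiers < n2)]] = 1.85
    fold[de_local[tiers >= n2]] = 1.6
    return pd.DataFrame(
        {
            "gene": [gene_ids[i] for i in idx],
            "fold_change": fold,
            "flagged": flags,
        }
    )


def simulate_expression(
    gene_ids: list[str],
    flagged: np.ndarray,
    odds_ratio: float,
    n_de: tuple[int, int, int, int] = (88, 214, 520, 14140),
    n_splice: tuple[int, int, int, int] = (123, 278, 613, 13208),
    seed: int = 0,
) -> pd.DataFrame:
    """Expression/splicing table in which flagged genes (those carrying
    coding/UTR/splice SNVs) are enriched among DE and spliced genes.

    Returns columns ``gene``, ``fold_change`` and ``splice_p``; tier
    sizes default to the study conditions (cumulative fold-change tiers
    88/214/520 against 14140 not-DE genes; splicing-significance tiers
    123/278/613 against 13208).
    """
    rng = np.random.default_rng(seed)
    expr = assign_expression_categories(gene_ids, flagged, odds_ratio, n_de, rng)
    flag_map = dict(zip(expr["gene"], expr["flagged"]))
    sub_ids = list(expr["gene"])
    sub_flags = np.array([flag_map[g] for g in sub_ids])
    n1, n2, n3, n_null = n_splice
    total = n3 + n_null
    if total > len(sub_ids):
        raise ConfigurationError(
            f"splicing category sizes need {total} genes, only {len(sub_ids)} available"
        )
    idx = (
        rng.choice(len(sub_ids), size=total, replace=False)
        if total < len(sub_ids)
        else np.arange(len(sub_ids))
    )
    weights = np.where(sub_flags[idx], float(odds_ratio), 1.0)
    keys = np.log(weights) + rng.gumbel(size=total)
    order = np.argsort(-keys)
    spliced_local = order[:n3]
    tiers = rng.permutation(n3)
    pvals = np.full(total, 0.5)
    pvals[spliced_local[tiers < n1]] = 1e-6
    pvals[spliced_local[(tiers >= n1) & (tiers < n2)]] = 1e-3
    pvals[spliced_local[tiers >= n2]] = 0.05
    splice_p = pd.Series(np.nan, index=range(len(sub_ids)))
    splice_p.iloc[idx] = pvals
    expr = expr.drop(columns=["flagged"])
    expr["splice_p"] = splice_p.to_numpy()
    return expr
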