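"""Readers and writers for the pipeline's interchange formats.

Standard formats go through standard libraries (FASTA via Biopython,
GFF3 via gffutils, VCF reading via cyvcf2); the bespoke pileup-summary
TSV, read-start bedGraph and panel/expression tables are plain
tab-separated text.  Coordinates follow each format's own convention:
VCF and the pileup TSV are 1-based, BED/bedGraph are 0-based half-open;
everything in memory is 0-based half-open.  Parsers validate strictly
and report the offending line and field.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from strainvar.annotate import ConservationTrack, GeneModel, TranscriptModel
from strainvar.calling import StrainCalls, VariantCall, VariantClass
from strainvar.pileup import (
    ChromPileup,
    Pileup,
    SITE_COLUMNS,
    SiteObservation,
    pileup_from_observations,
)


class ParseError(ValueError):
    def __init__(self, path, line_no: int, field: str, message: str):
        super().__init__(f"{path}:{line_no}: field {field!r}: {message}")
        self.line_no = line_no
        self.field = field


# ---------------------------------------------------------------- FASTA

def write_fasta(reference: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------- pileup TSV

PILEUP_HEADER = [
    "chrom",
    "pos_1based",
    "ref",
    "depth",
    "depth_nodup",
    "countA",
    "countC",
    "countG",
    "countT",
    "count_indel_allele",
    "indel_seq",
    "hq_count_alt",
]


def write_pileup_tsv(pileup: Pileup, path: str | Path, sparse_only: bool = True) -> None:
    """Write the per-site pileup summary.

    With ``sparse_only`` (default) only sites carrying non-reference
    evidence are written; dense depth tracks travel separately as
    bedGraph.  With ``sparse_only=False`` every covered position gets a
    row (small fixtures only).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(PILEUP_HEADER) + "\n")
        for chrom in sorted(pileup.chroms):
            cp = pileup.chroms[chrom]
            sparse = {int(p): i for i, p in enumerate(cp.sites["pos"])}
            rows = cp.sites
            if sparse_only:
                for row in rows.itertuples(index=False):
                    fh.write(
                        f"{chrom}\t{int(row.pos) + 1}\t{row.ref}\t{int(row.depth)}\t"
                        f"{int(row.depth_nodup)}\t{int(row.countA)}\t{int(row.countC)}\t"
                        f"{int(row.countG)}\t{int(row.countT)}\t"
                        f"{int(row.count_indel_allele)}\t{row.indel_seq or '.'}\t"
                        f"{int(row.hq_count_alt)}\n"
                    )
            else:
                for pos in range(cp.length):
                    if pos in sparse:
                        row = rows.iloc[sparse[pos]]
                        fh.write(
                            f"{chrom}\t{pos + 1}\t{row['ref']}\t{int(row['depth'])}\t"
                            f"{int(row['depth_nodup'])}\t{int(row['countA'])}\t"
                            f"{int(row['countC'])}\t{int(row['countG'])}\t"
                            f"{int(row['countT'])}\t{int(row['count_indel_allele'])}\t"
                            f"{row['indel_seq'] or '.'}\t{int(row['hq_count_alt'])}\n"
                        )
                    else:
                        d = int(cp.depth[pos])
                        dn = int(cp.depth_nodup[pos])
                        fh.write(
                            f"{chrom}\t{pos + 1}\tN\t{d}\t{dn}\t0\t0\t0\t0\t0\t.\t0\n"
                        )


def read_pileup_tsv(
    path: str | Path,
    strain: str,
    chrom_lengths: dict[str, int],
    reference: dict[str, str] | None = None,
) -> Pileup:
    """Load a pileup summary TSV (validates every field)."""
    obs: list[SiteObservation] = []
    depth: dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()
    }
    nodup: dict[str, np.ndarray] = {
        c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()
    }
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PILEUP_HEADER:
            raise ParseError(path, 1, "header", f"expected {PILEUP_HEADER}")
        for line_no, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(PILEUP_HEADER):
                raise ParseError(
                    path, line_no, "row", f"expected {len(PILEUP_HEADER)} columns"
                )
            chrom = parts[0]
            if chrom not in chrom_lengths:
                raise ParseError(path, line_no, "chrom", f"unknown chromosome {chrom}")
            try:
                pos = int(parts[1]) - 1
            except ValueError:
                raise ParseError(path, line_no, "pos_1based", "not an integer")
            if not 0 <= pos < chrom_lengths[chrom]:
                raise ParseError(path, line_no, "pos_1based", "outside chromosome")
            ints = {}
            for field in (
                "depth",
                "depth_nodup",
                "countA",
                "countC",
                "countG",
                "countT",
                "count_indel_allele",
                "hq_count_alt",
            ):
                raw = parts[PILEUP_HEADER.index(field)]
                try:
                    value = int(raw)
                except ValueError:
                    raise ParseError(path, line_no, field, f"not an integer: {raw!r}")
                if value < 0:
                    raise ParseError(path, line_no, field, "negative count")
                ints[field] = value
            if ints["depth_nodup"] > ints["depth"]:
                raise ParseError(
                    path, line_no, "depth_nodup", "exceeds duplicate-inclusive depth"
                )
            ref_base = parts[2]
            if reference is not None and ref_base != "N":
                actual = reference[chrom][pos]
                if actual != ref_base:
                    raise ParseError(
                        path, line_no, "ref", f"reference has {actual!r}"
                    )
            indel_seq = "" if parts[10] in (".", "") else parts[10]
            if indel_seq and indel_seq[0] not in "+-":
                raise ParseError(path, line_no, "indel_seq", "must start with + or -")
            depth[chrom][pos] = ints["depth"]
            nodup[chrom][pos] = ints["depth_nodup"]
            if (
                any(ints[f"count{b}"] for b in "ACGT")
                or ints["count_indel_allele"]
                or ref_base != "N"
            ):
                obs.append(
                    SiteObservation(
                        chrom=chrom,
                        pos=pos,
                        ref=ref_base,
                        depth=ints["depth"],
                        depth_nodup=ints["depth_nodup"],
                        counts={b: ints[f"count{b}"] for b in "ACGT"},
                        indel_count=ints["count_indel_allele"],
                        indel_seq=indel_seq,
                        hq_count_alt=ints["hq_count_alt"],
                    )
                )
    pu = pileup_from_observations(strain, obs, chrom_lengths)
    for chrom in pu.chroms:
        pu.chroms[chrom].depth = depth[chrom]
        pu.chroms[chrom].depth_nodup = nodup[chrom]
    return pu


# ------------------------------------------------------------- bedGraph

def write_bedgraph(track: dict[str, np.ndarray], path: str | Path) -> None:
    """Run-length-encoded per-position values (0-based half-open)."""
    with open(path, "w") as fh:
        for chrom in sorted(track):
            arr = np.asarray(track[chrom])
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                value = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{chrom}\t{s}\t{e}\t{value}\n")


def read_bedgraph(
    path: str | Path,
    chrom_lengths: dict[str, int],
    dtype=np.int32,
) -> dict[str, np.ndarray]:
    track = {c: np.zeros(n, dtype=dtype) for c, n in chrom_lengths.items()}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith(("track", "#")) or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(path, line_no, "row", "expected 4 columns")
            chrom, s_raw, e_raw, v_raw = parts
            if chrom not in chrom_lengths:
                raise ParseError(path, line_no, "chrom", f"unknown chromosome {chrom}")
            try:
                s, e = int(s_raw), int(e_raw)
            except ValueError:
                raise ParseError(path, line_no, "start/end", "not integers")
            if not 0 <= s < e <= chrom_lengths[chrom]:
                raise ParseError(
                    path, line_no, "start/end", f"invalid interval {s}-{e}"
                )
            try:
                v = float(v_raw)
            except ValueError:
                raise ParseError(path, line_no, "value", f"not numeric: {v_raw!r}")
            track[chrom][s:e] = v
    return track


# ------------------------------------------------------- conservation

def write_conservation(track: ConservationTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, rows in sorted(track.intervals().items()):
            for s, e, v in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")


def read_conservation(path: str | Path) -> ConservationTrack:
    """Conservation scores from bedGraph or fixedStep wiggle."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("fixedStep"):
        return _read_wiggle(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ParseError(path, line_no, "row", "expected 4 columns")
            chrom, s_raw, e_raw, v_raw = parts
            try:
                s, e, v = int(s_raw), int(e_raw), float(v_raw)
            except ValueError:
                raise ParseError(path, line_no, "row", "bad numeric field")
            if e <= s:
                raise ParseError(path, line_no, "start/end", "empty interval")
            if not 0.0 <= v <= 1.0:
                raise ParseError(path, line_no, "value", "score outside [0, 1]")
            intervals.setdefault(chrom, []).append((s, e, v))
    return ConservationTrack(intervals)


def _read_wiggle(path: str | Path) -> ConservationTrack:
    """fixedStep wiggle: 1-based start, per-position scores."""
    intervals: dict[str, list[tuple[int, int, float]]] = {}
    chrom, pos, step, span = None, 0, 1, 1
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(
                    part.split("=", 1) for part in line.split()[1:]
                )
                try:
                    chrom = fields["chrom"]
                    pos = int(fields["start"]) - 1
                    step = int(fields.get("step", 1))
                    span = int(fields.get("span", 1))
                except (KeyError, ValueError):
                    raise ParseError(path, line_no, "fixedStep", "bad declaration")
                continue
            if chrom is None:
                raise ParseError(path, line_no, "row", "value before fixedStep header")
            try:
                v = float(line)
            except ValueError:
                raise ParseError(path, line_no, "value", f"not numeric: {line!r}")
            if not 0.0 <= v <= 1.0:
                raise ParseError(path, line_no, "value", "score outside [0, 1]")
            intervals.setdefault(chrom, []).append((pos, pos + span, v))
            pos += step
    return ConservationTrack(intervals)


# ------------------------------------------------------------------ VCF

def write_vcf(
    calls: StrainCalls,
    path: str | Path,
    chrom_lengths: dict[str, int],
    annotations: dict[tuple[str, int], str] | None = None,
    conservation: dict[tuple[str, int], float] | None = None,
) -> None:
    """VCF 4.2 with DP, SUPP, HQ (and optional CSQ/CONS) INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=strainvar\n")
        for chrom in sorted(chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={chrom_lengths[chrom]}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Duplicate-free depth">\n')
        fh.write('##INFO=<ID=SUPP,Number=1,Type=Float,Description="Support fraction">\n')
        fh.write('##INFO=<ID=HQ,Number=0,Type=Flag,Description="Depth >= high-quality cutoff">\n')
        if annotations is not None:
            fh.write(
                '##INFO=<ID=CSQ,Number=1,Type=String,Description="category|transcript|gene">\n'
            )
        if conservation is not None:
            fh.write('##INFO=<ID=CONS,Number=1,Type=Float,Description="Conservation score">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for key in sorted(calls.calls):
            call = calls.calls[key]
            info = [f"DP={call.depth}", f"SUPP={call.support_fraction:.4f}"]
            if call.high_quality:
                info.append("HQ")
            if annotations is not None and key in annotations:
                info.append(f"CSQ={annotations[key]}")
            if conservation is not None and key in conservation:
                info.append(f"CONS={conservation[key]:.3f}")
            fh.write(
                f"{call.chrom}\t{call.pos + 1}\t.\t{call.ref}\t{call.alt}\t.\t"
                f"PASS\t{';'.join(info)}\n"
            )


def read_vcf(path: str | Path, strain: str = "") -> StrainCalls:
    """Read calls back from VCF (via cyvcf2)."""
    from cyvcf2 import VCF

    result = StrainCalls(strain=strain)
    vcf = VCF(str(path))
    for rec in vcf:
        ref = rec.REF
        alt = rec.ALT[0]
        if len(ref) == len(alt) == 1:
            vclass = VariantClass.SNV
        elif len(alt) > len(ref):
            vclass = VariantClass.INSERTION
        else:
            vclass = VariantClass.DELETION
        pos = rec.POS - 1
        depth = int(rec.INFO.get("DP", 0) or 0)
        supp = float(rec.INFO.get("SUPP", 0.0) or 0.0)
        hq = rec.INFO.get("HQ") is not None
        result.calls[(rec.CHROM, pos)] = VariantCall(
            chrom=rec.CHROM,
            pos=pos,
            ref=ref,
            alt=alt,
            variant_class=vclass,
            depth=depth,
            support_fraction=supp,
            high_quality=hq,
        )
    vcf.close()
    return result


# ------------------------------------------------------------------ BED

def write_bed(
    rows: list[tuple],
    path: str | Path,
) -> None:
    """Write BED rows: (chrom, start, end[, name[, score[, strand]]])."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | Path) -> list[tuple]:
    rows: list[tuple] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ParseError(path, line_no, "row", "fewer than 3 columns")
            try:
                s, e = int(parts[1]), int(parts[2])
            except ValueError:
                raise ParseError(path, line_no, "start/end", "not integers")
            if e <= s:
                raise ParseError(
                    path, line_no, "start/end", f"empty or inverted interval {s}-{e}"
                )
            rows.append((parts[0], s, e, *parts[3:]))
    return rows


# ----------------------------------------------------------------- GFF3

def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Gene models as GFF3 (gene / mRNA / exon / CDS features)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            fh.write(
                f"{gene.chrom}\tstrainvar\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                fh.write(
                    f"{tx.chrom}\tstrainvar\tmRNA\t{tx.start + 1}\t{tx.end}\t.\t"
                    f"{tx.strand}\t.\tID={tx.transcript_id};Parent={gene.gene_id}\n"
                )
                for i, (s, e) in enumerate(tx.exons, 1):
                    fh.write(
                        f"{tx.chrom}\tstrainvar\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                        f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}\n"
                    )
                for i, (s, e) in enumerate(tx.cds, 1):
                    fh.write(
                        f"{tx.chrom}\tstrainvar\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t0\t"
                        f"ID={tx.transcript_id}.cds{i};Parent={tx.transcript_id}\n"
                    )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models through gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="mRNA"):
            exons = [
                (f.start - 1, f.end) for f in db.children(t, featuretype="exon")
            ]
            cds = [(f.start - 1, f.end) for f in db.children(t, featuretype="CDS")]
            transcripts.append(
                TranscriptModel(
                    transcript_id=t.id,
                    gene_id=g.id,
                    chrom=t.seqid,
                    strand=t.strand,
                    exons=sorted(exons),
                    cds=sorted(cds),
                )
            )
        genes.append(GeneModel(g.id, g.seqid, g.strand, transcripts))
    return genes


# ------------------------------------------------------------- tables

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth_cnv_bed(truth, path: str | Path) -> None:
    rows = [
        (chrom, start, end, f"copy{copy}") for chrom, start, end, copy in truth.cnvs
    ]
    write_bed(rows, path)
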