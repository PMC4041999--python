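"""Pileup containers: per-position allele counts for one strain.

A :class:`Pileup` stores, per chromosome, dense depth tracks (raw and
duplicate-free) plus a sparse table holding every site with non-reference
evidence (or any site at all when loaded from a full pileup TSV).  The
sparse columns mirror the pileup summary TSV dialect::

    chrom pos_1based ref depth depth_nodup countA countC countG countT
    count_indel_allele indel_seq hq_count_alt

All allele-count columns are over the duplicate-collapsed read set;
duplicate reads contribute only to the raw ``depth`` column.
``hq_count_alt`` is the number of supporting reads with base quality
above the calling threshold for the dominant non-reference allele at the
site (SNV base or indel allele, whichever has the higher duplicate-free
count; base ties break alphabetically and an indel never beats a tied
base).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

#: dtype of the sparse site table
SITE_COLUMNS = {
    "pos": np.int64,  # 0-based
    "ref": object,
    "depth": np.int32,
    "depth_nodup": np.int32,
    "countA": np.int32,
    "countC": np.int32,
    "countG": np.int32,
    "countT": np.int32,
    "count_indel_allele": np.int32,
    "indel_seq": object,  # "+SEQ" insertion / "-SEQ" deletion / ""
    "hq_count_alt": np.int32,
}


@dataclass
class SiteObservation:
    """One pileup site: allele counts and qualities for one strain.

    Counts are over the duplicate-collapsed read set; ``depth`` includes
    duplicate reads, ``depth_nodup`` does not.
    """

    chrom: str
    pos: int  # 0-based
    ref: str
    depth: int
    depth_nodup: int
    counts: dict[str, int] = field(default_factory=dict)  # base -> dedup count
    indel_count: int = 0
    indel_seq: str = ""  # "+SEQ" or "-SEQ"
    hq_count_alt: int = 0

    def __post_init__(self) -> None:
        for base, n in self.counts.items():
            if n > self.depth_nodup:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: count[{base}]={n} exceeds "
                    f"duplicate-free depth {self.depth_nodup}"
                )
        if self.depth_nodup > self.depth:
            raise ValueError(
                f"{self.chrom}:{self.pos}: depth_nodup {self.depth_nodup} "
                f"exceeds depth {self.depth}"
            )


@dataclass
class ChromPileup:
    """Dense depth tracks plus sparse evidence sites for one chromosome."""

    length: int
    depth: np.ndarray  # raw depth incl. duplicates, int32
    depth_nodup: np.ndarray  # duplicate-free depth, int32
    sites: pd.DataFrame  # SITE_COLUMNS schema, sorted by pos


@dataclass
class Pileup:
    """Per-strain pileup: one :class:`ChromPileup` per chromosome."""

    strain: str
    chroms: dict[str, ChromPileup]

    def site_observations(self) -> list[SiteObservation]:
        """Materialize the sparse sites as :class:`SiteObservation` rows."""
        out: list[SiteObservation] = []
        for chrom in sorted(self.chroms):
            cp = self.chroms[chrom]
            for row in cp.sites.itertuples(index=False):
                out.append(
                    SiteObservation(
                        chrom=chrom,
                        pos=int(row.pos),
                        ref=str(row.ref),
                        depth=int(row.depth),
                        depth_nodup=int(row.depth_nodup),
                        counts={
                            "A": int(row.countA),
                            "C": int(row.countC),
                            "G": int(row.countG),
                            "T": int(row.countT),
                        },
                        indel_count=int(row.count_indel_allele),
                        indel_seq=str(row.indel_seq),
                        hq_count_alt=int(row.hq_count_alt),
                    )
                )
        return out


def empty_sites() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in SITE_COLUMNS.items()})


def sites_from_observations(obs: list[SiteObservation]) -> pd.DataFrame:
    """Build a sparse site table from observation rows (one chromosome)."""
    if not obs:
        return empty_sites()
    data = {
        "pos": [o.pos for o in obs],
        "ref": [o.ref for o in obs],
        "depth": [o.depth for o in obs],
        "depth_nodup": [o.depth_nodup for o in obs],
        "countA": [o.counts.get("A", 0) for o in obs],
        "countC": [o.counts.get("C", 0) for o in obs],
        "countG": [o.counts.get("G", 0) for o in obs],
        "countT": [o.counts.get("T", 0) for o in obs],
        "count_indel_allele": [o.indel_count for o in obs],
        "indel_seq": [o.indel_seq for o in obs],
        "hq_count_alt": [o.hq_count_alt for o in obs],
    }
    df = pd.DataFrame(data)
    return df.astype({c: t for c, t in SITE_COLUMNS.items()}).sort_values(
        "pos", kind="stable", ignore_index=True
    )


def pileup_from_observations(
    strain: str, obs: list[SiteObservation], chrom_lengths: dict[str, int]
) -> Pileup:
    """Assemble a :class:`Pileup` from per-site observations.

    Dense depth tracks are zero except at the observed sites — suitable
    for fixtures and for pileups loaded from sparse TSVs.
    """
    chroms: dict[str, ChromPileup] = {}
    by_chrom: dict[str, list[SiteObservation]] = {c: [] for c in chrom_lengths}
    for o in obs:
        if o.chrom not in by_chrom:
            raise ValueError(f"observation on unknown chromosome {o.chrom}")
        by_chrom[o.chrom].append(o)
    for chrom, length in chrom_lengths.items():
        depth = np.zeros(length, dtype=np.int32)
        nodup = np.zeros(length, dtype=np.int32)
        rows = by_chrom[chrom]
        for o in rows:
            if not 0 <= o.pos < length:
                raise ValueError(f"position {o.pos} outside {chrom} (len {length})")
            depth[o.pos] = o.depth
            nodup[o.pos] = o.depth_nodup
        chroms[chrom] = ChromPileup(
            length=length,
            depth=depth,
            depth_nodup=nodup,
            sites=sites_from_observations(rows),
        )
    return Pileup(strain=strain, chroms=chroms)
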