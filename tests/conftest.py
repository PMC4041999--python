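"""Shared fixtures: small simulated studies and hand-built gene fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from strainvar.annotate import GeneModel, TranscriptModel
from strainvar.config import SimulationConfig
from strainvar.pileup import SiteObservation
from strainvar.simulate import simulate_pileup, simulate_strains


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        chromosome_lengths={"chr1": 300_000}, snv_rate=1e-3, seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    """Two strains with pileups on a 300 kb genome."""
    reference, truths = simulate_strains(small_config, 2)
    pileups = {}
    tracks = {}
    for truth in truths:
        pu, st = simulate_pileup(reference, truth, small_config)
        pileups[truth.name] = pu
        tracks[truth.name] = st
    return reference, truths, pileups, tracks


def make_site(
    ref: str = "A",
    depth_nodup: int = 20,
    counts: dict[str, int] | None = None,
    indel_count: int = 0,
    indel_seq: str = "",
    hq: int | None = None,
    depth: int | None = None,
    chrom: str = "chr1",
    pos: int = 0,
) -> SiteObservation:
    """Site builder; by default every supporting read passes the quality cut."""
    counts = counts or {}
    nonref = {b: c for b, c in counts.items() if b != ref and c > 0}
    dom = max(nonref.values()) if nonref else 0
    if indel_count > dom:
        dom = indel_count
    return SiteObservation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        depth=depth if depth is not None else depth_nodup,
        depth_nodup=depth_nodup,
        counts=counts,
        indel_count=indel_count,
        indel_seq=indel_seq,
        hq_count_alt=hq if hq is not None else dom,
    )


@pytest.fixture(scope="session")
def plus_gene():
    """A small + strand gene with 5'UTR / 3-exon CDS / 3'UTR on a fixed
    sequence, plus a second transcript skipping the middle exon."""
    # exon1 100-200 (CDS from 130), exon2 300-400, exon3 500-620 (CDS to 561)
    tx1 = TranscriptModel(
        "T1", "G1", "chr1", "+", exons=[(100, 200), (300, 400), (500, 620)],
        cds=[(130, 200), (300, 400), (500, 561)],
    )
    assert tx1.cds_length % 3 == 0
    tx2 = TranscriptModel(
        "T2", "G1", "chr1", "+", exons=[(100, 200), (500, 620)],
        cds=[(130, 200), (500, 559)],
    )
    assert tx2.cds_length % 3 == 0
    return GeneModel("G1", "chr1", "+", [tx1, tx2])


@pytest.fixture(scope="session")
def fixed_sequence():
    """Deterministic 1 kb sequence for the hand-built gene fixtures."""
    rng = np.random.default_rng(2024)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=1000))}
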