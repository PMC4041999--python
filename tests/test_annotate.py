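"""Consequence-classifier tests: codon oracle, splice geometry, strand
invariance, conservation flag boundaries."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq

from strainvar.annotate import (
    Category,
    ConservationTrack,
    GeneModel,
    TranscriptModel,
    classify_variant,
    gene_level,
    is_conserved,
    severity_rank,
    summarize_consequences,
    GeneLevelConsequence,
)
from strainvar.calling import VariantCall, VariantClass
from strainvar.config import AnnotationParams, SimulationConfig
from strainvar.simulate import simulate_genes, simulate_reference


def snv(pos, ref, alt, chrom="chr1"):
    return VariantCall(chrom, pos, ref, alt, VariantClass.SNV, 20, 1.0)


def retranslation_oracle(tx: TranscriptModel, variant: VariantCall, chrom_seq: str):
    """Independent oracle: rebuild the whole mutant CDS, translate both
    proteins, and classify from the first differing residue."""
    mutant = (
        chrom_seq[: variant.pos] + variant.alt + chrom_seq[variant.pos + 1 :]
    )
    p_ref = str(Seq(tx.cds_sequence(chrom_seq)).translate())
    p_alt = str(Seq(tx.cds_sequence(mutant)).translate())
    if p_ref == p_alt:
        return Category.SYNONYMOUS
    for a, b in zip(p_ref, p_alt):
        if a != b:
            if b == "*":
                return Category.STOP_GAINED
            if a == "*":
                return Category.STOP_LOST
            return Category.NON_SYNONYMOUS
    return Category.SYNONYMOUS


def tx_category(consequences, tx_id):
    return [c.category for c in consequences if c.transcript_id == tx_id][0]


class TestCodonClassification:
    def _one_gene(self, seq, strand="+"):
        tx = TranscriptModel("T1", "G1", "chr1", strand, [(0, len(seq))], [(0, len(seq))])
        return GeneModel("G1", "chr1", strand, [tx]), {"chr1": seq}

    def test_caa_to_taa_is_stop_gained(self):
        gene, ref = self._one_gene("ATGCAAGGGTAA")
        cats = classify_variant(snv(3, "C", "T"), [gene], ref)
        assert cats[0].category is Category.STOP_GAINED

    def test_stop_lost(self):
        gene, ref = self._one_gene("ATGCAATAAGGG")
        cats = classify_variant(snv(6, "T", "C"), [gene], ref)
        assert cats[0].category is Category.STOP_LOST

    def test_third_position_gct_to_gcc_is_synonymous(self):
        gene, ref = self._one_gene("ATGGCTGGGTAA")
        cats = classify_variant(snv(5, "T", "C"), [gene], ref)
        assert cats[0].category is Category.SYNONYMOUS

    def test_minus_strand_uses_reverse_complement(self):
        # genomic TTACAT reverse-complements to ATGTAA: ATG then stop
        gene, ref = self._one_gene("TTACAT", strand="-")
        # genomic position 1 (T) is codon 2 base 2 on the - strand;
        # T>C makes TAA -> TGA? verify simply against the oracle
        want = retranslation_oracle(gene.transcripts[0], snv(1, "T", "C"), "TTACAT")
        got = classify_variant(snv(1, "T", "C"), [gene], ref)[0].category
        assert got is want

    def test_reference_mismatch_raises(self):
        gene, ref = self._one_gene("ATGCAAGGGTAA")
        with pytest.raises(ValueError, match="mismatch"):
            classify_variant(snv(3, "G", "T"), [gene], ref)

    def test_frameshift_indel_noted(self):
        gene, ref = self._one_gene("ATGCAAGGGTAA")
        ins = VariantCall("chr1", 3, "C", "CAG", VariantClass.INSERTION, 20, 1.0)
        cons = classify_variant(ins, [gene], ref)
        assert cons[0].category is Category.NON_SYNONYMOUS
        assert cons[0].note == "frameshift"
        inframe = VariantCall("chr1", 3, "CAAG", "C", VariantClass.DELETION, 20, 1.0)
        cons = classify_variant(inframe, [gene], ref)
        assert cons[0].note == "inframe"


class TestStrandInvariance:
    def test_mirror_fixture_agrees_with_plus_strand(self):
        """Classifying on a - strand gene equals classifying the
        reverse-complemented variant on the mirrored + strand gene."""
        rng = np.random.default_rng(7)
        L = 300
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
        exons = [(30, 90), (150, 240)]
        cds = [(36, 90), (150, 231)]
        minus_tx = TranscriptModel("Tm", "Gm", "chr1", "-", exons, cds)
        minus_gene = GeneModel("Gm", "chr1", "-", [minus_tx])
        mirror_seq = str(Seq(seq).reverse_complement())
        m_exons = sorted((L - e, L - s) for s, e in exons)
        m_cds = sorted((L - e, L - s) for s, e in cds)
        plus_tx = TranscriptModel("Tp", "Gp", "chr1", "+", m_exons, m_cds)
        plus_gene = GeneModel("Gp", "chr1", "+", [plus_tx])
        for pos in range(30, 240):
            ref_b = seq[pos]
            alt_b = "ACGT"[("ACGT".index(ref_b) + 1) % 4]
            minus_cat = tx_category(
                classify_variant(snv(pos, ref_b, alt_b), [minus_gene], {"chr1": seq}),
                "Tm",
            )
            m_pos = L - 1 - pos
            m_ref = str(Seq(ref_b).complement())
            m_alt = str(Seq(alt_b).complement())
            plus_cat = tx_category(
                classify_variant(
                    snv(m_pos, m_ref, m_alt), [plus_gene], {"chr1": mirror_seq}
                ),
                "Tp",
            )
            assert minus_cat is plus_cat, f"position {pos}"


class TestSpliceAndRegionGeometry:
    @pytest.fixture
    def gene(self, plus_gene):
        return plus_gene

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (200, Category.ESSENTIAL_SPLICE_SITE),  # first intron base
            (201, Category.ESSENTIAL_SPLICE_SITE),
            (202, Category.SPLICE_SITE),  # 3rd..8th intron base
            (207, Category.SPLICE_SITE),
            (208, Category.INTRONIC),
            (298, Category.ESSENTIAL_SPLICE_SITE),  # last 2 bases of intron
            (292, Category.SPLICE_SITE),
            (291, Category.INTRONIC),
        ],
    )
    def test_intron_side_widths(self, gene, fixed_sequence, pos, expected):
        ref_b = fixed_sequence["chr1"][pos]
        alt_b = "A" if ref_b != "A" else "C"
        cats = classify_variant(snv(pos, ref_b, alt_b), [gene], fixed_sequence)
        assert tx_category(cats, "T1") is expected

    @pytest.mark.parametrize(
        "pos, expected",
        [
            (105, Category.UTR5),  # exonic, before CDS start, + strand
            (570, Category.UTR3),  # exonic, after CDS end
            (617, Category.UTR3),  # 3' UTR not near a junction
        ],
    )
    def test_utr_assignment(self, gene, fixed_sequence, pos, expected):
        ref_b = fixed_sequence["chr1"][pos]
        alt_b = "A" if ref_b != "A" else "C"
        cats = classify_variant(snv(pos, ref_b, alt_b), [gene], fixed_sequence)
        assert tx_category(cats, "T1") is expected

    def test_exon_side_splice_region_in_utr(self, gene, fixed_sequence):
        # last 3 exonic bases before an intron are splice region; here
        # the 5' UTR ends at 130 and exon1 runs to 200 (all CDS after
        # 130), so use exon3's start: positions 500-502 are CDS -> the
        # coding category wins; check a UTR exon edge instead on T2
        pos = 198  # inside CDS: coding wins
        ref_b = fixed_sequence["chr1"][pos]
        alt_b = "A" if ref_b != "A" else "C"
        cats = classify_variant(snv(pos, ref_b, alt_b), [gene], fixed_sequence)
        assert tx_category(cats, "T1") in CODING


CODING = {
    Category.STOP_GAINED,
    Category.STOP_LOST,
    Category.NON_SYNONYMOUS,
    Category.SYNONYMOUS,
}


class TestFlanksAndGeneLevel:
    def test_upstream_downstream_and_intergenic(self, plus_gene, fixed_sequence):
        params = AnnotationParams(flank_bp=50)
        up = classify_variant(
            snv(60, fixed_sequence["chr1"][60], "A" if fixed_sequence["chr1"][60] != "A" else "C"),
            [plus_gene], fixed_sequence, params,
        )
        assert {c.category for c in up} == {Category.UPSTREAM}
        down = classify_variant(
            snv(650, fixed_sequence["chr1"][650], "A" if fixed_sequence["chr1"][650] != "A" else "C"),
            [plus_gene], fixed_sequence, params,
        )
        assert {c.category for c in down} == {Category.DOWNSTREAM}
        away = classify_variant(
            snv(900, fixed_sequence["chr1"][900], "A" if fixed_sequence["chr1"][900] != "A" else "C"),
            [plus_gene], fixed_sequence, params,
        )
        assert [c.category for c in away] == [Category.INTERGENIC]

    def test_alternative_transcript_partial_stop(self, plus_gene, fixed_sequence):
        """A variant in the skipped exon affects T1 but not T2's CDS."""
        pos = 350  # inside exon2, which transcript T2 skips
        ref_b = fixed_sequence["chr1"][pos]
        alt_b = "A" if ref_b != "A" else "C"
        cons = classify_variant(snv(pos, ref_b, alt_b), [plus_gene], fixed_sequence)
        t1 = tx_category(cons, "T1")
        t2 = tx_category(cons, "T2")
        assert t1 in CODING
        assert t2 is Category.INTRONIC
        gl = gene_level(cons, {"G1": plus_gene})
        assert gl.total_transcripts == 2
        assert gl.affected_transcripts < gl.total_transcripts

    def test_exactly_one_gene_level_category(self, plus_gene, fixed_sequence):
        seq = fixed_sequence["chr1"]
        for pos in range(100, 620, 7):
            ref_b = seq[pos]
            alt_b = "A" if ref_b != "A" else "C"
            cons = classify_variant(snv(pos, ref_b, alt_b), [plus_gene], fixed_sequence)
            per_tx = {}
            for c in cons:
                assert per_tx.setdefault(c.transcript_id, c.category) is c.category
            gl = gene_level(cons, {"G1": plus_gene})
            assert gl.category is min(
                (c.category for c in cons), key=severity_rank
            )


class TestRetranslationOracleSweep:
    def test_random_variants_match_oracle_both_strands(self, small_config):
        """Classification of random coding variants on simulated genes
        (both strands) agrees with whole-CDS retranslation."""
        ref = simulate_reference(small_config)
        genes = simulate_genes(ref, small_config, n_genes=12)
        rng = np.random.default_rng(41)
        checked = 0
        for gene in genes:
            seq = ref[gene.chrom]
            for tx in gene.transcripts:
                for s, e in tx.cds:
                    for _ in range(8):
                        pos = int(rng.integers(s, e))
                        ref_b = seq[pos]
                        alt_b = rng.choice([b for b in "ACGT" if b != ref_b])
                        v = snv(pos, ref_b, alt_b, chrom=gene.chrom)
                        got = tx_category(
                            classify_variant(v, [gene], ref), tx.transcript_id
                        )
                        assert got is retranslation_oracle(tx, v, seq)
                        checked += 1
        assert checked >= 300


class TestConservation:
    def test_strictly_greater_than_threshold(self):
        track = ConservationTrack({"chr1": [(100, 200, 0.45), (300, 400, 0.1)]})
        assert is_conserved(snv(150, "A", "C"), track)  # score 0.45
        assert not is_conserved(snv(350, "A", "C"), track)  # exactly 0.1
        assert not is_conserved(snv(500, "A", "C"), track)  # missing -> 0

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            ConservationTrack({"chr1": [(0, 10, 1.5)]})


class TestSummarize:
    def test_empty_input_gives_all_zero_table(self):
        table = summarize_consequences({"S1": []})
        assert (table["S1"] == 0).all()

    def test_hand_tally(self):
        records = [
            GeneLevelConsequence(Category.STOP_GAINED, "G1", 1, 1),
            GeneLevelConsequence(Category.NON_SYNONYMOUS, "G1", 1, 1),
            GeneLevelConsequence(Category.NON_SYNONYMOUS, "G2", 1, 1),
            GeneLevelConsequence(Category.SYNONYMOUS, "G2", 1, 1),
            GeneLevelConsequence(Category.INTRONIC, "G3", 1, 1),
        ]
        table = summarize_consequences({"S1": records})
        assert table.loc["stop_gained", "S1"] == 1
        assert table.loc["non_synonymous", "S1"] == 2
        assert table.loc["synonymous", "S1"] == 1
        assert table.loc["intronic", "S1"] == 1
        assert table["S1"].sum() == 5
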