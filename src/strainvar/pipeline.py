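"""End-to-end orchestration: simulate → call → compare → cnv → annotate
→ enrich → report.

``run_pipeline`` wires the stages together on simulated data with known
truth and writes every product to an artifact directory as standard
formats (VCF, BED, bedGraph, GFF3, TSV) plus a run log recording the
effective parameters.  Re-running with the same configuration
reproduces byte-identical outputs (the log's timestamps aside).
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path

import pandas as pd

from strainvar import formats
from strainvar.annotate import gene_level, classify_variant, is_conserved
from strainvar.calling import StrainCalls, VariantCall, VariantClass, build_eve_blacklist, call_strain
from strainvar.cnv import detect_cnvs
from strainvar.compare import (
    detect_differentiating_regions,
    find_unique_snvs,
    match_ancestry,
    partition_sharing,
)
from strainvar.config import PipelineConfig
from strainvar.enrich import build_feature_flags, enrichment_table
from strainvar.qtl import QtlInterval, build_report
from strainvar.simulate import (
    MosaicSegment,
    simulate_conservation,
    simulate_genes,
    simulate_genotype_panel,
    simulate_pileup,
    simulate_strains,
    simulate_expression,
)


def _truth_to_calls(truth) -> StrainCalls:
    sc = StrainCalls(strain=truth.name)
    for chrom, pos, ref, alt in truth.snvs | truth.indels:
        if len(ref) == len(alt) == 1:
            vclass = VariantClass.SNV
        elif len(alt) > len(ref):
            vclass = VariantClass.INSERTION
        else:
            vclass = VariantClass.DELETION
        sc.calls[(chrom, pos)] = VariantCall(
            chrom, pos, ref, alt, vclass, 0, 1.0
        )
    return sc


def default_tier_sizes(n_genes: int) -> tuple[int, int, int, int]:
    """Scale the cumulative DE tier sizes down to a small gene set."""
    n1 = max(1, n_genes // 100)
    n2 = max(n1 + 1, n_genes // 40)
    n3 = max(n2 + 1, n_genes // 15)
    return (n1, n2, n3, n_genes - n3)


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path | None = None,
    n_genes: int = 60,
) -> Path:
    """Run every stage on a simulated study and write all artifacts.

    Simulates ``config.n_strains`` strains (the first two as a mosaic
    sub-strain pair with implanted divergent segments and one deletion/
    duplication pair between them) plus a resequenced reference
    individual carrying a sprinkling of reference errors for the
    blacklist.  Returns the artifact directory.
    """
    out = Path(out_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        log_lines.append(f"{stamp} {msg}")

    log(f"config: {dataclasses.asdict(config)}")

    sim = config.simulation
    chrom_lengths = sim.chromosome_lengths
    chrom, clen = next(iter(chrom_lengths.items()))
    n = max(config.n_strains, 2)
    names = [f"S{i + 1}" for i in range(n)]
    segments = [
        MosaicSegment(chrom, int(clen * 0.4), int(clen * 0.6), "ANC1", "ANC2")
    ]
    cnvs = {
        names[1]: [
            (chrom, int(clen * 0.05), int(clen * 0.10), 0),
            (chrom, int(clen * 0.80), int(clen * 0.85), 2),
        ]
    }
    reference, truths = simulate_strains(
        config.simulation,
        n,
        mosaic_pairs=[(names[0], names[1], segments)],
        cnvs=cnvs,
        strain_names=names,
    )
    formats.write_fasta(reference, out / "reference.fa")

    # resequenced reference individual: no true variants, but a few
    # planted reference errors to feed the blacklist
    eve_cfg = dataclasses.replace(
        config.simulation,
        snv_rate=config.simulation.snv_rate * 0.01,
        indel_rate=0.0,
        het_site_fraction=0.0,
    )
    _, (eve_truth,) = simulate_strains(eve_cfg, 1, strain_names=["Eve"])
    eve_pileup, _ = simulate_pileup(reference, eve_truth, eve_cfg)
    blacklist = build_eve_blacklist(eve_pileup, config.calling)
    formats.write_table(
        pd.DataFrame(sorted(blacklist), columns=["chrom", "pos"]),
        out / "blacklist.tsv",
    )
    log(f"blacklist: {len(blacklist)} positions")

    all_calls: list[StrainCalls] = []
    start_tracks = {}
    for truth in truths:
        pileup, starts = simulate_pileup(reference, truth, config.simulation)
        start_tracks[truth.name] = starts
        formats.write_pileup_tsv(pileup, out / f"{truth.name}.pileup.tsv")
        formats.write_bedgraph(starts, out / f"{truth.name}.starts.bedgraph")
        formats.write_vcf(
            _truth_to_calls(truth), out / f"{truth.name}.truth.vcf", chrom_lengths
        )
        formats.write_truth_cnv_bed(truth, out / f"{truth.name}.truth_cnv.bed")
        calls = call_strain(pileup, blacklist, config.calling)
        all_calls.append(calls)
        log(
            f"{truth.name}: {calls.stats.n_calls} calls, "
            f"{calls.stats.n_het_excluded} heterozygous-excluded, "
            f"{calls.stats.n_blacklist_removed} blacklisted"
        )

    genes = simulate_genes(reference, config.simulation, n_genes=n_genes)
    formats.write_gff3(genes, out / "genes.gff3")
    conservation = simulate_conservation(reference, config.simulation)
    formats.write_conservation(conservation, out / "conservation.bedgraph")

    genes_by_id = {g.gene_id: g for g in genes}
    per_strain_cons = {}
    for calls in all_calls:
        annos = {}
        cons_scores = {}
        records = []
        for key, call in sorted(calls.calls.items()):
            cons_list = classify_variant(call, genes, reference, config.annotation)
            gl = gene_level(cons_list, genes_by_id)
            records.append((call, gl))
            annos[key] = f"{gl.category.value}|{gl.affected_transcripts}of{gl.total_transcripts}|{gl.gene_id}"
            cons_scores[key] = conservation.score_at(*key)
        per_strain_cons[calls.strain] = records
        formats.write_vcf(
            calls,
            out / f"{calls.strain}.calls.vcf",
            chrom_lengths,
            annotations=annos,
            conservation=cons_scores,
        )
        formats.write_table(
            pd.DataFrame(sorted(calls.het_positions), columns=["chrom", "pos"]),
            out / f"{calls.strain}.het_excluded.tsv",
        )

    partition = partition_sharing(all_calls, config.comparison.sharing_min_coverage)
    rows = [
        {
            "strains": "+".join(sorted(subset)),
            "count": count,
            "fraction": partition.fractions[subset],
        }
        for subset, count in sorted(
            partition.counts.items(), key=lambda kv: (-kv[1], sorted(kv[0]))
        )
    ]
    formats.write_table(pd.DataFrame(rows), out / "sharing_partition.tsv")
    log(
        f"sharing: {partition.analyzed_positions} analyzed, "
        f"{partition.excluded_positions} excluded"
    )

    cnv_calls = detect_cnvs(
        start_tracks[names[0]], start_tracks[names[1]], config.cnv
    )
    formats.write_bed(
        [
            (
                c.chrom,
                c.start,
                c.end,
                c.cnv_class.value,
                int(1000 * min(c.mean_ratio, 2) / 2),
            )
            for c in cnv_calls
        ],
        out / "cnv.bed",
    )
    formats.write_table(
        pd.DataFrame(
            [
                {
                    "chrom": c.chrom,
                    "start": c.start,
                    "end": c.end,
                    "class": c.cnv_class.value,
                    "mean_ratio": round(c.mean_ratio, 4),
                    "uncovered_a": round(c.uncovered_a, 4),
                    "uncovered_b": round(c.uncovered_b, 4),
                }
                for c in cnv_calls
            ]
        ),
        out / "cnv.tsv",
    )
    log(f"cnv: {len(cnv_calls)} calls between {names[0]} and {names[1]}")

    regions = detect_differentiating_regions(
        all_calls[0], all_calls[1], config.comparison
    )
    panel = simulate_genotype_panel(
        truths, n_markers=min(2000, clen // 200), reference=reference, config=sim
    )
    formats.write_table(panel, out / "genotype_panel.tsv")
    region_rows = []
    for region in regions:
        try:
            match_ancestry(region, all_calls[0], all_calls[1], panel, config.comparison)
        except ValueError:
            pass
        region_rows.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "snv_count": region.snv_count,
                "density_per_mbp": round(region.density_per_mbp, 2),
                "ancestors_a": ",".join(
                    a for a, _i in region.matched_ancestors.get(names[0], [])
                ),
                "ancestors_b": ",".join(
                    a for a, _i in region.matched_ancestors.get(names[1], [])
                ),
            }
        )
    formats.write_bed(
        [(r.chrom, r.start, r.end, f"region{i+1}") for i, r in enumerate(regions)],
        out / "differentiating_regions.bed",
    )
    formats.write_table(pd.DataFrame(region_rows), out / "differentiating_regions.tsv")
    log(f"regions: {len(regions)} differentiating regions")

    # enrichment on the first strain's gene-level consequences
    gene_ids = [g.gene_id for g in genes]
    flags = build_feature_flags(
        gene_ids, [gl for _c, gl in per_strain_cons[names[0]]]
    )
    tier = default_tier_sizes(len(gene_ids))
    expr = simulate_expression(
        gene_ids,
        flags[["coding", "utr", "splice"]].any(axis=1).to_numpy(),
        odds_ratio=3.0,
        n_de=tier,
        n_splice=tier,
        seed=config.seed,
    )
    formats.write_table(expr, out / "expression.tsv")
    enr = enrichment_table(flags, expr, config.enrichment)
    formats.write_table(enr, out / "enrichment.tsv")

    unique = find_unique_snvs([names[0]], all_calls)
    intervals = [
        QtlInterval(
            "Qtl1", chrom, 0, clen // 2, (names[0],), tuple(names[2:]) or (names[1],)
        ),
        QtlInterval(
            "Qtl2", chrom, clen // 2, clen, (names[0],), tuple(names[2:]) or (names[1],)
        ),
    ]
    consequences = {
        (call.chrom, call.pos): gl
        for recs in per_strain_cons.values()
        for call, gl in recs
    }
    qtl_rows = []
    for interval in intervals:
        report = build_report(
            interval,
            all_calls,
            consequences,
            conservation,
            unique.unique,
            genes,
            config.annotation.conservation_threshold,
        )
        qtl_rows.append(
            {
                "qtl": interval.name,
                "chrom": interval.chrom,
                "start": interval.start,
                "end": interval.end,
                "genes": report.n_genes,
                "genes_with_coding_snvs": report.n_genes_with_coding_snvs,
                "ns_snvs": report.n_ns_snvs,
                "stop_snvs": report.n_stop_snvs,
                "splice_snvs": report.n_splice_snvs,
                "indels": report.n_indels,
                "conserved_snvs": len(report.conserved_snvs),
                "unique_snvs": len(report.unique_snvs),
                "segregating": report.n_segregating,
            }
        )
    formats.write_table(pd.DataFrame(qtl_rows), out / "qtl_report.tsv")
    log("pipeline complete")

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
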