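# Methods

This note records the models, parameter choices and numerical decisions
behind `strainvar`, in the spirit of a methods appendix: what each stage
assumes, why its defaults are what they are, and what the simulation-based
tests do and do not demonstrate about real data.

## Variant-calling model

The caller operates on per-site pileup summaries, not reads. Its central
assumption is that the sample is an inbred line, homozygous at essentially
every locus; true variants should therefore be supported by nearly all
reads, and intermediate allele balance is evidence of trouble (unfixed
residual heterozygosity, collapsed duplications, mismapping) rather than of
a diploid genotype.

Per site, with duplicates removed first (reads sharing a start position are
counted once; allele counts are defined over the duplicate-free read set):

- dominant non-reference allele: the base or indel allele with the highest
  duplicate-free count. Base ties break alphabetically; an indel must
  strictly exceed the best base to become the candidate; indels of 10 bp or
  longer are never candidates (the pipeline's scope is short indels).
- `n` = duplicate-free depth, `k` = supporting reads with base quality
  above 10, `f = k/n`.
- homozygous call iff `k >= min_calls` (3) and `f >= min_support` (0.75
  for SNVs, 0.40 for indels). The boundary belongs to the call: `f`
  exactly at the threshold with `k` sufficient is a call, not an
  exclusion.
- otherwise heterozygous-excluded iff `0.25 <= f <` the class's support
  threshold. For indels this makes the band [0.25, 0.40). Excluded
  positions are tallied and exported; downstream sharing analyses drop
  them genome-wide.
- otherwise reference; zero depth is a separate no-data outcome. The four
  outcomes partition every site.

The support fraction's denominator is the full duplicate-free depth;
quality filtering applies only to the numerator's supporting calls. This is
the only reading consistent with requiring both "three quality calls" and
"75% of the reads".

Positions at which a resequenced individual of the reference strain itself
passes the variant call are blacklisted everywhere: a "variant" in the
very animal the reference was assembled from is almost surely an assembly
error. The blacklist applies to SNVs and indels alike.

Calls at duplicate-free depth >= 8 are flagged high-quality; per-strain
statistics include the genome fraction covered by >= 3 and >= 8 reads,
which is what makes sensitivity figures interpretable.

`call_strain` is a vectorized implementation; its contract, enforced by
test, is exact agreement with independent per-site evaluation of the rules
above.

## CNV model

Copy-number detection compares two strains' unique-read-start tracks.
Windows hold a fixed count of strain-A read starts (default 500), so
window size adapts to coverage and the Poisson counting noise per window is
constant — this is the point of dynamic windows. Window boundaries fall on
whole positions, so a window can overshoot the target by the multiplicity
of its last position; the final window of a chromosome may be short.

The per-window statistic is the library-size-normalized ratio
`(count_B / count_A) x (total_A / total_B)`. Windows below 0.3 seed
deletions in B; windows above 1.6 seed either duplications in B or
deletions in A — the two are separated by strain A's read-start density
relative to its genome mean (below half the mean ⇒ deletion in A). Runs
of same-class windows merge into calls; runs shorter than
`min_event_windows` (2) are dropped as single-window noise, except that a
single window whose genomic span is at least `min_event_windows` times the
expected window span is kept — a deletion in strain A necessarily
manifests as one huge window, not several.

Two filters follow. (i) Coverage band: at least one strain's mean coverage
inside the call must lie within ±0.5× of its genome mean; regions where
both strains sit far from their means behave like collapsed repeats. The
"at least one" reading is a deliberate choice where "one strain" is
ambiguous. (ii) Deletions must show uncovered-base fractions differing by
at least 10 percentage points between the strains; per-base coverage is
reconstructed from read starts with a fixed read length (default 50 bp).

## Consequence classification

Twelve mutually exclusive categories per (variant, transcript), with a
fixed severity order (stop_gained > stop_lost > non_synonymous >
synonymous > essential_splice_site > splice_site > utr5 > utr3 >
intronic > upstream > downstream > intergenic). Within a transcript,
coding status takes precedence: a CDS base that is also within the
exon-side splice region is classified by its codon. Coding SNVs are
classified by strand-aware single-codon translation; a tested invariant is
exact agreement with a brute-force oracle that rebuilds the whole mutant
CDS and compares the translated proteins.

Splice geometry follows the conventional definitions: the first and last
two intronic bases of each intron are essential splice sites; the wider
splice region covers 3 exonic and 8 intronic bases at each junction. Gene
flanks default to 5000 bp for upstream/downstream assignment. All three
widths are parameters (`AnnotationParams`) because annotation tools vary
here and no single convention is canonical.

CDS-overlapping indels are reported as non_synonymous with a
`frameshift` note when their length change is not a multiple of three
(`inframe` otherwise); frameshift is an annotation note, not a
thirteenth category, keeping the category partition intact.

The gene-level category of a variant is the most severe across the gene's
transcripts, together with affected/total transcript counts — a premature
stop predicted only in an alternatively spliced isoform is visible as
affected < total.

Conservation: a variant is conserved iff its per-base score (phastCons-like,
in [0, 1], missing positions scoring 0) is **strictly** greater than the
threshold, default 0.1. A score of exactly 0.1 is not conserved.

## Multi-strain comparison

The sharing partition assigns each SNV position to the subset of strains
carrying a non-reference allele there, after excluding positions where any
strain is heterozygous-excluded or covered by fewer than 3 reads. Counts
plus exclusions are conserved (excluded + analyzed = total) and fractions
sum to one over non-empty subsets. Indel calls are not part of the
partition.

Differentiating regions between two sub-strains are fixed 100 kb windows
whose count of genotype-differing positions (both strains covered by >= 8
reads) exceeds 100 differences per Mbp, merged across gaps of at most one
below-threshold window. Window size, density threshold and merge gap are
package choices, tuned to megabase-scale divergent segments against an
essentially identical background; they are parameters because the
genome-wide divergence of other strain pairs will differ.

Ancestry matching computes, over panel markers inside a region, each
sub-strain's identity to every panel genotype column, counting
reference-allele matches as informative, and reports all panel strains
within 0.02 of the best identity — the tie margin exists so that several
equally matching ancestors are reported together rather than an arbitrary
single winner.

Unique variants: present with identical alternate allele in every target
strain, absent from every non-target genome covered by >= 3 reads at the
position; positions any non-target genome cannot resolve are reported
separately as unresolved rather than silently counted either way.

## Enrichment analysis

Genes are flagged for carrying coding ({stop_*, non_synonymous,
synonymous}), UTR ({utr5, utr3}) or splice ({splice_site,
essential_splice_site}) SNVs at gene-level category. Expression tiers are
cumulative (a fold-change > 2 gene is also in the > 1.7 and > 1.5 tiers),
matching the monotone tier counts such tables print; each tier is compared
to the unregulated baseline in a 2x2 table with a two-sided Fisher exact
test, reporting the sample odds ratio (unbounded tables report infinity).
Genes absent from the expression table are excluded from numerator and
denominator. Fisher's exact test is the natural choice for tier sizes as
small as ~90 genes against a ~14,000-gene baseline.

## The synthetic-data generator

The generator produces the study conditions the filters were designed for:

- genomes: uniform-random reference sequence; per-strain SNVs (default
  1e-3/bp), short indels (1e-4/bp, 1-9 bp), residual heterozygous loci
  (1e-3/bp, 50/50 allele mix), explicit copy-number events (copy 0 or 2).
- coverage: duplicate-free depth Poisson(20) per site, scaled by the local
  copy multiplier (0 in homozygous deletions, 2 in duplications);
  read-start tracks Poisson(coverage/read length) per position. The real
  study's median coverage was 18–22X, hence the 20X default.
- noise: each read miscalls its base with probability 0.01 to a uniform
  other base; base qualities are two-point (30 with probability 0.99,
  else 5), so ~99% of calls pass the "> 10" cut — the calling rules use
  qualities only through that cut, so a richer quality model would be
  unidentifiable here; duplicates (5%) inflate raw depth only.
- sub-strain pairs: mosaic construction — strain B carries exactly strain
  A's variants outside declared ancestry segments and independently drawn
  variants inside them, with per-segment donor labels that the genotype
  panel's synthetic ancestor columns reproduce (matching the strain
  fully inside donated segments, at 50% outside).
- expression tables: DE/splicing tiers of configurable sizes (defaults
  are the study's 88/214/520/14140 and 123/278/613/13208) assigned by
  weighted sampling without replacement (Gumbel top-k), with flagged
  genes entering at a configurable odds ratio.

Everything derives from one integer seed through tagged child generators,
so identical configurations are byte-deterministic.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: mapping ambiguity and repeat structure
(reads are implicitly uniquely mapped; the coverage-band CNV filter is
exercised only by synthetic density scaling), sequencing-technology error
profiles (errors are i.i.d. uniform; real miscalls are context-dependent
and correlated), alignment artifacts around indels, GC-coverage bias, and
linkage structure in heterozygous residue (simulated uniformly at random,
as its genomic distribution is not known). Sensitivity numbers on
simulated data are accordingly upper bounds on real-data performance.

## Numerical and design choices

- "Quality > 10" is interpreted as per-base call quality; mapping quality
  is out of scope of a pileup-level strategy.
- Multi-allelic sites: only the dominant non-reference allele is tested;
  minor alleles are ignored.
- Degenerate inputs: zero-depth sites are no-data; empty pileups yield
  empty call sets and zero statistics; an empty strain-A track yields no
  CNV windows; sharing with fewer than two strains, identity with no
  in-region markers and sensitivity with no differing markers raise
  errors rather than returning conventional values.
- Pipeline determinism: artifact files are byte-identical across reruns of
  the same configuration; the run log (which carries ISO timestamps) is
  the only exception.
- QTL reports count the union of contrast-strain variants inside the
  interval, with "segregating" formalized as strict biallelic separation:
  every susceptible strain shares one allele, every resistant strain the
  other, positions under-covered or heterozygous-excluded in any contrast
  strain skipped. Candidate ranking is a fixed deterministic order
  (premature stops, essential splice, non-synonymous, splice region,
  conserved non-coding by descending score, UTR, rest; ties by position).

## Test problem sizes

The simulation-based checks run at deliberately modest scales chosen to
make their statistics decisive: sensitivity on a 10 Mb genome with
~10,000 truth SNVs (binomial s.e. ~0.2% at 97%); heterozygosity exclusion
on ~1,000 simulated 50/50 sites; CNV recovery of 100 kb implants on 1 Mb;
differentiating-region recovery of eight 1 Mb segments on 26 Mb;
enrichment calibration with 1,000 null replicates at the study's tier
sizes; the sharing partition on 500 kb across four strains. The partition
check runs with the heterozygous-residue rate set to zero because it
asserts exact set equality against truth algebra, and a 50/50 site escapes
the exclusion band by binomial sampling ~2% of the time at 20X — the
exclusion rule itself is exercised by its dedicated check.

## Known limitations

- The caller consumes pileup summaries; BAM/FASTQ ingestion, realignment,
  genotype likelihoods and phasing are out of scope.
- The consequence classifier is deliberately minimal: no regulatory
  features, protein-domain mapping or deleteriousness scores.
- CNV classes are limited to homozygous deletion and single duplication;
  ratio thresholds are not calibrated for higher copy numbers.
- Differentiating-region detection is a density scan, not a local-ancestry
  HMM; region boundaries are window-quantized.
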