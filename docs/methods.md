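# Methods

## Scope and design

`editome` is a site-level re-implementation of an RNA-editome analysis:
it starts from per-sample pileup columns (position, reference base, and
one observed base + read offset per read) rather than from BAMs. Upstream
read processing — alignment, duplicate marking, realignment, base
recalibration — is out of scope; the simplified pileup TSV is the
ingestion surface, and a naive per-alternate mismatch caller (≥ 2
supporting reads after the read-start trim) stands in for a full
genotyper. All internal coordinates are 1-based inclusive; BED input is
converted at the boundary.

## Filter cascade

Filters run in a fixed order — known-SNP subtraction, read-position trim
(applied during calling), splice proximity, homopolymer, multi-locus —
and each removed site is attributed to exactly one filter in a trace
whose counts are conserved. The order affects only attribution, not the
surviving set, because each filter's predicate is independent of the
others. Decisions taken where the underlying references were silent:

* **SNP matching** defaults to *position-only* (any candidate at a known
  SNP position is removed), the conservative reading of database
  subtraction; an allele-aware mode is available.
* **"Within 4 bp of a splice junction"** is read as distance ≤ 4
  inclusive, measured in bases to the nearest annotated internal exon
  boundary on either side (exonic or intronic); distance 5 survives. The
  window is configurable.
* **Homopolymer** removal covers sites inside *or immediately adjacent
  (±1) to* a maximal run of ≥ 5 identical reference bases, because
  errors at run boundaries are the dominant artifact mode; adjacency is
  configurable.
* **Multi-locus** detection replaces a BLAT search with exact 20-mer
  seeding plus Hamming verification: a site is removed if the
  (2·50+1)-bp window around it occurs at a second locus (either strand)
  with ≤ 2 mismatches. Non-overlapping seeds make detection exhaustive
  at that threshold (≤ 2 mismatches cannot hit all seeds), and the scan
  is verified against an exhaustive all-window comparison in tests. At
  contig edges the window shrinks symmetrically. These parameters are
  declared substitutes for a similarity search, not a reproduction of
  BLAT's scoring.

## Quantification and classification

Editing ratio is alternate depth over total depth, both counted after
discarding observations whose offset in the read is ≤ 6; the trim removes
reference and alternate support alike, so the ratio stays unbiased. A
sample is "edited" at a site iff it passes the high-confidence gate
there (depth ≥ 10 and ratio > 0.2, both strict as stated); this
operationalizes "percentage of samples edited".

Substitution family uses the unsigned pair rule — A>G and T>C are both
the ADAR (A-to-I) signature, C>T and G>A the APOBEC (C-to-U) signature —
without resolving transcriptional strand first, which keeps intergenic
sites classifiable. Gene strand is consulted only for coding effects,
where the codon is rebuilt from the spliced CDS on the transcript strand
(genomic alleles complemented for minus-strand genes) and translated with
the standard code. When transcripts overlap, the effect is reported for
the first coding transcript (lexicographic id) whose CDS covers the
site. Region classification applies the precedence CDS-exonic > UTR >
ncRNA > intronic > 5′flank > intergenic; the 5′flank is the `flank_bp`
(default 1000, configurable) bases upstream of a transcript start on its
strand. Repeat context is Alu > non-Alu repeat > non-repeat, with Alu
identified by the RepeatMasker-style name prefix "Alu".

## Differential editing

Group summaries use covered samples only (depth ≥ `min_depth`); sites
with fewer than `min_covered = 5` covered samples in either group are
untestable and excluded from the BH family, which is all testable sites
within one comparison. The Mann–Whitney test enumerates the exact
permutation null (ties handled via midranks in doubled-integer
arithmetic) when n₁+n₂ ≤ 16 and otherwise uses the normal approximation
with tie and continuity corrections; the corrected approximation tracks
the exact p to within ~0.01 in the decision-relevant range (its worst
error, ~0.011, sits near p ≈ 0.5). All three significance criteria are
strict inequalities. Concordance between two differential tables is
keyed by (chrom, pos, ref, alt, direction) and reported under both
normalizations, since "fraction of the validation set recovered" and
"fraction of the discovery set confirmed" differ.

Editing–expression correlation defaults to Pearson (Spearman available);
the choice is exposed because the source analyses of this kind rarely
state it. Constant vectors yield NA rather than an error.

## Enrichment

Gene-set enrichment is a transparent one-sided Fisher exact test per GMT
set against a user-supplied background, BH-corrected across sets, with
sets of fewer than 3 background members skipped. The pipeline's default
background is all genes bearing at least one testable editing site. This
is a methodological substitute for web-service GO tools (which use
proprietary scores and unstated backgrounds), not a reproduction.
Multi-dataset commonality reports the full Venn region decomposition;
region counts sum to the union size by construction.

## Synthetic cohort

The generator emulates the cohort structure the pipeline targets:

* **Genome** (default 2 × 100 kb): multi-exon coding genes on both
  strands with UTRs and frame-0 CDS (length forced divisible by 3),
  ncRNA genes, ~300 bp Alu-like copies of a single consensus each
  independently diverged at 10% per base (including guaranteed inverted
  pairs in introns, mimicking the double-stranded RNA substrate of
  ADAR), non-Alu repeat copies, homopolymer runs of 5–8, and one exactly
  duplicated 200 bp intergenic locus pair. The 10% divergence keeps
  distinct Alu copies ~18% mismatched pairwise, far above the 2-mismatch
  multi-locus threshold, as in real genomes where BLAT does not collapse
  Alu elements.
* **Signal**: editing sites are A/T reference positions with the
  transition alternate, placed with probability `alu_bias = 0.9` inside
  Alu intervals, plus a small quota (4) planted directly in CDS so
  coding effects are exercised; per-sample true ratios are drawn from
  Beta(8,2) (mean 0.8) for controls and Beta(2,6) (mean 0.25) for
  tumors. The low-skewed tumor Beta puts most tumor samples below the
  0.2 gate, reproducing the characteristic collapse of
  percent-of-samples-edited (tens of percent in control vs a few percent
  in tumor) rather than a mild mean shift. Germline SNPs get allelic
  ratio 0.5 in carriers (carrier frequency 0.3), so that only the
  SNP-list subtraction — not any ratio heuristic — removes them.
* **Artifacts**, 20 per class: splice-proximal (distance 1–4 from a
  junction), homopolymer (inside/adjacent to a planted run),
  multi-locus (deep inside the duplicated locus so the ±50 bp window
  lies entirely within it), and hexamer-only (geometrically clean, but
  every alternate read is given offset ≤ 6). Placement enforces that
  each artifact violates exactly its own filter's predicate, and clean
  edits violate none, so filter attribution on synthetic data is exact
  by construction and any attribution error is the pipeline's.
* **Reads**: depth per site per sample ~ NegativeBinomial(mean 30,
  dispersion 5), matching RNA-seq overdispersion; alternate count ~
  Binomial(depth, true ratio); remaining reference reads flip to a
  uniform other base (never the planted alternate) at `base_error_rate
  = 0.001`; offsets uniform over a 100 bp read. Pileups are emitted at
  planted sites plus 200 background positions — not genome-wide — which
  is sufficient for a site-level pipeline and keeps cohorts desk-scale.

Everything is deterministic under a fixed seed; each stage draws from a
stream forked by stage name (SeedSequence keyed on a CRC of the name), so
toggling one stage never perturbs another's draws. The validation cohort
for concordance keeps the same genome and planted sites but redraws
per-sample ratios and reads from independent streams — two cohorts over
the same biology.

What the generator does *not* model: read-level alignment (no FASTQ, no
splicing-aware mapping artifacts), RNA secondary structure, hyper-editing
clusters, base-quality variation, batch effects, or empirically estimated
per-grade ratio distributions (the Betas are stated knobs, not
estimates). Passing tests therefore demonstrate correctness of the
filtering/testing machinery under a faithful noise model, not performance
on real cohorts, whose artifact spectrum is broader.

## Problem sizes and numerics

The default test and acceptance workloads are a 200 kb genome with 40
samples and ~410 covered sites per sample; the differential benchmark
uses 200 null + 100 shifted sites at 20 vs 20 samples over 10 replicates;
ratio recovery uses depth 100 and 50 samples. These sizes give stable
statistics (binomial 99% bands, BH behavior at hundreds of tests) while
a full run stays in seconds. Fractions in distribution tables sum to 1
within 1e−9; BH q-values are capped at 1; editing ratios at zero depth
are NA and propagate as NA through tables (serialized as the literal
string `NA`). Run artifacts are byte-deterministic under fixed
config+seed; the run report additionally records wall times and is the
one file excluded from that guarantee.

## Known limitations

* The multi-locus filter checks a single window length and mismatch
  budget; it is not a general aligner and will miss duplications with
  indels.
* Coding effects report one transcript per site; overlapping isoforms
  with different frames are resolved by id order, not expression.
* The enrichment background must be supplied (or defaults to
  editing-testable genes); no GO DAG structure is used.
* Untestable (low-coverage) sites are excluded before BH; whether to
  include them is a genuine analytical choice and is configurable only
  by lowering `min_covered`.
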