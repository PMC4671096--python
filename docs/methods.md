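# Methods

## Scope and data model

`vcbench` scores single-sample diploid callsets (VCF 4.x, fields CHROM, POS,
REF, ALT, QUAL, FILTER, GT, DP) against a gold-standard callset inside an
evaluation territory given as BED intervals. Genotypes are stored as
unordered pairs of allele indices: every classification the package makes
(genotype concordance, IR/AR typing, Venn identity) is phase-free, so phase
is discarded at ingestion. Half-calls (`./1`) and non-diploid genotypes are
outside the model; they are skipped with a warning and counted, as are
hom-ref records (which assert no variant) and FILTER-failing records
(excluded by default, includable by flag — the convention for records the
upstream caller itself distrusts). Missing QUAL is kept missing, sorts below
any numeric QUAL, and fails every numeric threshold; coercing it to 0 would
silently promote unscored calls past a `qual_min` of 0. QUAL is quantized to
3 decimals on the record so values survive a float32 round-trip through the
VCF layer bit-exactly. Contig names match as exact strings ("chr1" ≠ "1");
silent prefix coercion hides real mismatches.

## Normalization to allelic primitives

Each record is split per called ALT (genotype indices remapped to {0,1};
uncalled ALTs dropped) and each REF/ALT pair is decomposed by global pairwise
alignment into primitives: single-base substitutions, and insertions/
deletions carrying a one-base anchor. Scoring is fixed — match +1, mismatch
−1, gap open −2, gap extend −1 (Gotoh affine-gap recursion) — with a
deterministic traceback that prefers a substitution column over a gap, and a
deletion over an insertion, at every tie. Fixed scores and tie-breaks make
decomposition reproducible; the exact parameters are a design choice, and
pathological complex alleles may decompose differently under other
normalizers. The test suite verifies optimality of the alignment score
against Biopython's `PairwiseAligner` configured identically.

Indels are left-aligned within the record's own REF string (stop at the
record's first base); no external reference genome is consulted, so shifts
never cross record boundaries. An indel at the very start of a record has no
left anchor; it is anchored on the following base instead, absorbing a
substitution made there by the alignment. Such leading primitives may not
share a first base between REF and ALT — the reconstruction property, not
the anchor convention, is the contract: substituting all primitives of one
ALT into REF reproduces that ALT exactly (property-tested on random allele
pairs up to length 30), and decomposition is idempotent. A primitive
produced by two different ALTs of one record is emitted once with a
homozygous-alt genotype. Primitives inherit the parent record's QUAL and
depth unchanged; there is no per-primitive quality model to inherit from.

## Evaluation territory

Intervals are held 0-based half-open (BED-native) and merged on
construction; VCF positions are converted once at ingestion. The territory
is the exact interval intersection of the high-confidence regions with the
capture regions. A variant is kept iff its reference span
`[pos−1, pos−1+len(ref))` is *fully contained* in one interval: mere overlap
would score half-in deletions against truth that was clipped at the same
edge. Restriction counts what it drops, so every downstream denominator is
auditable.

## Classification

Calls and truth join on `(chrom, pos, ref, alt)` after normalization and
restriction. Same key and genotype → TP; same key, different genotype →
genotyping error; unmatched call → FP; unmatched truth → FN. Duplicate keys
within one callset keep the highest-QUAL record (logged). One refinement:
a SNP call whose key is absent but whose site (`chrom, pos, ref`) holds an
unmatched truth SNP with a different ALT is a genotyping error, not an
FP+FN pair — that is the R/A-vs-R/B pattern of the OTHER class. Error
typing uses the *joint* site genotype (all primitives at the site), so an
alt/alt heterozygote represented as two het primitives is typed as A/B:

* IR — call {A,A}, truth {R,A} (same A);
* AR — call {R,A}, truth {A,A};
* OTHER — everything else.

Exhaustiveness and the IR↔AR mirror duality are brute-force-enumerated over
all unequal diploid genotype pairs on alleles {R, A, B}. Indel genotype
mismatches are genotyping errors but are not IR/AR-typed (the typology is
defined for SNPs); they carry the OTHER class and are excluded from the
IR/AR probability denominators, which count SNP calls only.

Genotyping errors are folded into FP for precision and FN for recall: the
emitted call is wrong *and* the truth genotype was not produced. This is the
strictest treatment consistent with a genotype-aware TP definition. The TN
universe — reported for completeness, unused by precision/recall — is the
covered territory length minus the number of truth sites.

## Metrics

* Precision = TP/(TP+FP+GE); defined as 1.0 when no calls survive (curves
  start at precision 1, and this convention measurably shifts APR on tiny
  inputs, so it is explicit). Recall = TP/(TP+FN+GE); an empty truth set is
  an error, not a 0.
* The PR curve sorts calls by descending QUAL; equal-QUAL calls are
  inseparable and form one threshold group (any within-tie order would be
  arbitrary). A truth site whose only call fell below the current threshold
  counts as missed at that threshold.
* APR is the step-wise average-precision sum Σ(Rᵢ−Rᵢ₋₁)·Pᵢ, clamped to
  [0,1]; no PR-space interpolation. Equality with scikit-learn's
  `average_precision_score` to 1e−9 is asserted on random tied score lists.
* The aligner-vs-caller decomposition takes, per (dataset, caller) group,
  the sample standard deviation (n−1) of APR across aligners, and
  symmetrically across callers, then averages; groups with fewer than two
  members are skipped with a warning.
* The het/hom depth ratio is the mean DP of correct het calls over the mean
  DP of correct hom-alt calls — a coverage-adequacy diagnostic (confident
  het calls need both alleles sampled).

## Concordance

Per caller, per-aligner callsets are merged by union over call identity
(best QUAL kept). Identity includes the genotype by default (a site called
het by one caller and hom-alt by another is discordant), with a
genotype-blind option. After filtering at QUAL ≥ 20 (missing QUAL fails),
every surviving call belongs to exactly one Venn region — the exact subset
of callers containing it — and regions are reported as percentages of the
union, then summarized as mean ± sd across datasets. The union is the
default denominator; per-dataset raw percentages are retained so any other
convention can be recomputed.

## The simulator

`simdata` emulates the benchmark's inputs, not sequencing physics. Confident
and capture BEDs are built by covering a fixed fraction of each 5 kb tiling
window at a random offset, which yields exact coverage fractions with
realistic fragmentation. Truth sites sit on a 10 bp grid inside
confident ∩ capture with a 6 bp margin from interval edges, so reference
spans (≤ 6 bp: anchor + up to 4 inserted/deleted bases, indel alleles 1–5 bp
with a one-base anchor) never straddle a region edge and neighbouring
primitives never interact. Reference bases are drawn uniformly from
{A,C,G,T}; no external genome is needed.

Query callsets degrade the truth per site, independently: dropped with
probability `fn_rate`; an emitted het becomes hom-alt with probability
`ir_rate`; an emitted hom-alt becomes het with `ar_rate`; an emitted SNP
otherwise has its ALT swapped with `other_rate`. `round(fp_rate·|truth|)`
novel SNP calls land on unused grid positions. Faithful calls draw QUAL from
N(45, 5) truncated at 0, erroneous ones from N(15, 5) — cleanly separated so
threshold filtering and QUAL ranking are meaningful; DP is Poisson with the
mean of the *emitted* genotype (defaults 80× het / 49× hom, an
exome-at-depth regime whose ratio ≈ 1.63 exercises the depth diagnostic;
genotype-flip errors therefore also shift the depth distribution). Default
rates (fn 3%, fp 2%, ir 1%, ar 1.5%, other 0.5%, 60% het, 4,000 SNPs + 400
indels on a 1.5 Mb contig) sketch a competent short-read pipeline on a
capture experiment. Every emitted call carries its intended label (TP / FP /
genotyping error + class; dropped truth as FN), and the label table is the
oracle the matcher is tested against, exactly, over randomized
configurations.

All randomness flows from one integer seed; per-callset streams derive from
(seed, CRC32 of the stream name), so multiple callsets from one truth are
independent but byte-reproducible, and identical seeds yield byte-identical
VCF/BED output.

What passing these tests shows — and does not: the pipeline recovers exactly
the labels of a generator whose errors are independent, uniformly placed and
representation-clean. Real callsets have clustered errors, correlated QUALs,
ambiguous indel representations near homopolymers, and truth-set biases;
agreement on simulated data validates the bookkeeping and the statistics,
not caller behaviour on real genomes.

## Problem sizes

Defaults were chosen so a full simulated benchmark (three datasets × six
pipelines, ~4,400 truth sites each) and the whole test suite run in well
under a minute each; rate-recovery checks use 20,000 sites, where three
binomial standard errors of a 5% rate is ±0.46 percentage points.

## Known limitations

No haplotype-level comparison (vcfeval-style phasing search) and no fuzzy
indel matching: matching is exact on the normalized representation, a
documented knob that will undercount concordance for representations this
normalizer cannot reconcile. Multi-sample VCFs, structural and symbolic
alleles, and BAM/FASTQ-level evidence are out of scope. Left-alignment is
per-record; truth and query normalized from very different complex
representations can still disagree at the key level.
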