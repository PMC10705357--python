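# Methods

## Scope and model

isoscope implements the structural-annotation half of a full-length
transcriptome experiment: everything downstream of CCS read generation
and genome alignment, and upstream of functional annotation and
differential expression. Alignment itself, error correction,
database searching and coding-potential model scoring are inputs
(SAM/BAM, TSV tables), not reimplemented; the package's own content is
the read classification, collapse/filter/locus logic, the AS/APA/fusion
rules and the lncRNA cascade.

Coordinates are 0-based half-open internally; GFF3 and BED I/O follow
their own conventions. A transcript's identity is its *junction chain*
— the ordered tuple of intron (donor, acceptor) coordinates — which is
robust to 5'/3' end scatter, the dominant noise mode of full-length
cDNA reads.

## FLNC classification

A read is oriented by terminal primer evidence (ungapped scan, ≤ m
mismatches, default m = 2 for 30 nt primers; both orientations scored,
ties → non-FL). The poly(A) tail is searched between the trimmed
termini: among terminal windows of length ≥ `min_len` (default 20) with
A-fraction ≥ `min_purity` (default 0.8), the accepted tail is the one
with the highest purity, ties to the longest — so a pure tail is
reported exactly, and genomic A's immediately preceding the tail are
(unavoidably) absorbed into it. A chimera is any read with an extra
primer hit ≥ 50 bp from both termini. The defaults are configurable;
none are dataset-fitted, and the error-free simulator is classified
perfectly under them, which is the design requirement.

## Collapse and filtering

Multi-exon reads collapse on exact (chrom, strand, chain). Mono-exon
reads merge transitively when spans overlap and 3' ends agree within
50 bp; the 5' end is left free, consistent with the degradation model.
Degradation filtering removes an isoform when its chain is a *strict*
3'-anchored suffix (genomic prefix on the minus strand) of a longer
same-strand isoform whose span strictly covers its 5' end. Two
deliberate edge decisions:

* Mono-exon isoforms are never degradation-filtered — an empty chain is
  a suffix of everything, and the literal rule would delete genuine
  single-exon genes nested in other genes' spans.
* The coverage test is strict (`other.start < victim.start`), so an
  intron-retention variant that shares the transcript start with the
  full-length form — whose chain *is* a suffix of the longer chain — is
  not mistaken for degradation.

Retention keeps isoforms with ≥ 2 reads, or 1 read with identity
> 0.99 (strict, interpreting the percent-identity threshold), or with
every intron supported by short-read junctions or the annotation. For
mono-exon isoforms the junction clause is false (there are no junctions
to support), not vacuously true, so unsupported mono-exon singletons do
not pass for free.

Loci are connected components of the pairwise relation "same chrom and
strand, span overlap ≥ 20% of the *shorter* span" — the symmetric
reading, which makes the transitive closure well defined. Novelty: a
locus is known when some reference gene satisfies that same relation;
an isoform is known on exact chain identity with a reference
transcript (mono-exon: chain identity is vacuous, so ≥ 20% span overlap
with a mono-exon reference transcript is required instead).

Reads split across multiple alignment records are routed to fusion
calling and excluded from collapse: a chimera's 5' segment would
otherwise surface as a spurious truncated isoform.

## AS events

Ten categories over isoform pairs of one locus. Exact patterns: SKIP /
MSKIP (an intron of one isoform containing 1 / ≥ 2 complete internal
exons of the other, flanking boundaries equal), IR / MIR (an exon of
one containing 1 / ≥ 2 complete introns of the other, outer boundaries
equal — boundaries that are transcript termini in both isoforms are
unconstrained, since cleavage positions are not splice sites), and AE
(two overlapping introns sharing exactly one boundary; intron pairs
where either intron contains a complete exon of the other isoform are
excluded, those being skipping patterns). When a pattern matches but a
constrained boundary differs by 1..fuzz bases (default 10, the figure
convention marks these only graphically) the X-prefixed approximate
type is emitted instead; with fuzz = 0 no X type can occur. Events are
symmetric in the pair and deduplicated per locus by (type, region);
the per-pair raw list is retained for audit.

## APA sites

Ends are taken from alignment block termini on the transcriptional 3'
side (tails are trimmed pre-alignment). Greedy grouping scans ends in
genomic order, opening a new cluster when the next end is more than
5 bp from the current cluster's representative — the modal position,
ties to the most 3'-distal for the strand. Clusters with < 2 reads are
dropped; acceptance is in descending support (ties most 3'-distal
first), skipping candidates within 15 bp of an accepted site. The
acceptance ordering is a documented choice — the rule "not within 15 bp
of a previous site" presupposes an order without stating one — and is
deterministic and input-order invariant. End-to-gene assignment allows
10 bp of slack beyond the annotated span because cleavage scatter
places ends slightly past gene boundaries.

## Fusion transcripts

Four criteria, each recorded per read for audit: (a) segments hit ≥ 2
annotated genes, every pair ≥ 10 kb apart or inter-chromosomal
(distance between nearest gene boundaries); (b) each per-gene merged
segment covers > 10% of the read; (c) combined coverage > 99%;
(d) paired-end junction support ≥ 2 (the support threshold is
configurable since "a certain amount" fixes none; evidence arrives as
a gene-pair count table). Multi-gene reads failing any criterion are
kept in the candidate table with the violated criteria listed.

## lncRNA cascade

Candidates must lack hits in all four protein databases, score below
the coding-potential cutoff (default 0.364, a common published
convention for CPAT-style scores; a boolean `coding_call` column can
bypass the score), and be ≥ 200 bp. Positional classes are assigned
with the precedence intergenic → intronic (full containment in a
single intron, either strand) → sense (candidate-exon vs
annotated-exon overlap, same strand) → antisense → other; the
precedence is a design choice the class definitions leave open. A
longest-ORF fraction is provided as a crude built-in score for
synthetic fixtures only.

## Report

Extensive columns (bases, read counts) are summed; intensive ones
(means, N50) never are. All percentages round half-up to two decimals,
matching how the bundled published tables print — with two documented
inconsistencies in those tables: the pooled FLNC percentage computes to
72.976% (printed truncated as 72.97), and the 2–3 kb locus bin count
was printed with transposed digits (8682; 8628 reconciles both the
stated 30,670 locus total and all four printed percentages, and is what
the bundled table carries, with a comment).

## Synthetic data generator

The generator emulates the study conditions: 3 chromosomes × 150 kb,
30 genes (20% noncoding), 2–4 isoforms per coding gene built by cycling
the five exact AS operations over a 4–8-exon base model, 1–3 APA sites
per gene spaced 40 bp, reads per isoform 2–6 with N(0, 2 bp) 3'-end
scatter, poly(A) tails of 20–40 nt, fixed 30 nt primers, 15% 5'-degraded
copies (trimmed to start mid-exon, preserving ≥ 1 intron), 2% fusion
reads (5' half of one gene + 3' half of another; ~80% inter-chromosomal,
the remainder ≥ 10 kb apart on one chromosome), 5% artifact reads
(cycling missing-5'-primer / missing-3'-primer / missing-tail /
internal-primer chimera), 25% of coding genes withheld from the
reference annotation (the study's reference lacked roughly half its
loci), and zero per-base error by default (substitution error is
configurable). Noncoding genes cycle through the five positional
placements so the lncRNA classifier is exercised on all of them; genes
hosting a placed noncoding transcript are never withheld, and fusion
partners are drawn from annotated genes only, since both novelty and
fusion criteria are defined against the annotation.

Determinism: one root `SeedSequence`, per-stage spawned children —
adding a stage never perturbs earlier stages; identical (seed, config)
gives byte-identical files. What the generator does *not* model:
realistic PacBio error profiles (errors are uniform substitutions),
quality scores, tissue-specific expression, internal priming, or
alignment ambiguity (alignments are written from the generating
models). Passing the recovery tests therefore shows the rules are
implemented exactly as specified and are mutually consistent — not
that they are robust to aligner artifacts or biased error modes in
real data.

## Problem sizes

Tests and the acceptance script run the generator at its defaults
(~30 genes, ~400–600 reads per run) plus two variants: a coding-only
run with 6–8 reads per isoform (so every APA site has ≥ 4 supporting
reads, the regime in which exact site-count recovery is the documented
expectation) and a high-degradation run (30%). Oracle-equivalence
suites use 500–1000 random instances per operation. These sizes were
chosen so each property is exercised across all strands, placements and
event types while a full run stays in the seconds range.
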