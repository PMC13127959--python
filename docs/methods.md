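# Methods

This note documents the model behind `txrefine`, the defaults and why they
are what they are, the synthetic data the tests run on, and the numerical
conventions a maintainer needs to know.

## The refinement model

The package operates on a gene → transcript → exon hierarchy read from GTF.
Coordinates are kept in GTF convention (1-based, closed) end to end; any
half-open arithmetic is private to the interval index and covered by
round-trip tests. Transcript length always means **spliced** length — the
sum of exon lengths — because it describes the mature transcript sequence,
not the genomic footprint. Features other than gene/transcript/exon (CDS,
UTRs, codons) are carried verbatim with their transcript and re-emitted
untouched; the tool refines gene models, it does not reinterpret coding
annotation. Both `key "value";` and `key=value` attribute syntaxes are
accepted on read; GTF2.2 is emitted on write, attributes in a fixed order
(`gene_id`, `transcript_id`, then sorted keys) so output is byte-stable.

Classification is a four-way partition driven by the number of reference
genes sharing exonic sequence with the candidate on the same strand
(0 → novel gene, 1 → exact match or novel isoform, ≥2 → join evidence).
Decisions that were genuinely open, and how they were settled:

* **Exon-level, not span-level, overlap.** A candidate wholly inside an
  intron overlaps no exon and is a novel gene. Span overlap would silently
  absorb intronic non-coding transcripts, which are exactly the kind of
  novelty worth keeping.
* **Antisense overlap does not link.** Opposite-strand overlap yields a
  novel gene, matching how reference-comparison tools treat antisense
  classes.
* **Unstranded candidates** (typically single-exon) match genes on either
  strand; if that produces hits on both strands the gene with the largest
  exonic overlap wins, ties broken by smaller gene start then identifier —
  deterministic and overlap-maximising.
* **Structural identity** is intron-chain equality. Single-exon transcripts
  have empty chains, so identity falls back to ≥ 80 % reciprocal exonic
  overlap with a single-exon reference isoform; the threshold is a tool
  parameter (`single_exon_reciprocal_overlap`).
* **One base of exonic overlap suffices to join genes.** The junction and
  expression filters upstream already guard against noise, and imposing an
  overlap floor here would make merge behaviour depend on exon sizes.

Merging is connected components over the gene graph (networkx), not
pairwise union: merged units of high cardinality need not be spanned by any
single transcript, so transitive closure is required. Components are
ordered by the genomic position of their leftmost member so identifier
assignment is reproducible. No adjacency constraint is imposed — a spanning
transcript may skip an intervening gene. Same-scaffold membership is forced
by the overlap definition; mixed-strand components are not forbidden (they
can arise from unstranded evidence) but cannot occur with stranded input.

Integration assigns fresh identifiers in genomic order, merge components
first, then novel loci, as `<prefix><zero-padded serial>` with default
prefix `GBIG_G_` and width 6; serials that would collide with existing ids
are skipped. Merged genes keep their members' transcript identifiers and
record provenance in a `merged_from` attribute. Novel transcripts are
clustered into gene loci by transitive same-strand exonic overlap and named
`<gene_id>.t<n>` in genomic order — a tool convention, since upstream
assemblers' transcript names carry no meaning after integration. Exact
matches contribute nothing, not even attribute updates. A novel-isoform
survivor whose host gene was consumed by a merge component it is not
evidence for is a hard consistency error rather than a silent re-attach:
it indicates the classification and merge inputs come from different
batches.

## Filters and their parameters

| parameter | default | meaning |
|---|---|---|
| `min_junction_reads` | 4 | spliced reads required at each novel junction |
| `min_anchor` | 15 bp | shortest aligned block flanking the junction |
| `min_coverage` | 10 | per-transcript assembler coverage floor |
| `min_sample_fraction` | 0.30 | fraction of samples with assigned expression |
| `min_total_reads` | 10 | expected counts summed over all samples |
| `min_gene_fraction` | 0.10 | share of the gene's reads owned by the transcript |

Junctions already present in the reference need no evidence. Evidence rows
with unknown strand match either orientation. A novel junction with no
evidence row counts as zero reads (it fails), not as an error. Candidates
without a coverage attribute skip the coverage rule — coverage is an
assembler-dialect extra, and its absence should not be fatal.

Expression semantics follow the filter's wording literally: "fewer than" /
"less than" are strict, so a transcript with exactly 10 reads, or expressed
in exactly 30 % of samples, or owning exactly 10 % of its gene's reads,
passes. "Expressed" means expected count strictly greater than zero — the
counts are fractional multi-mapping-resolved estimates and no additional
TPM cutoff is imposed. The sample fraction is real-valued, never rounded to
a sample count. The gene denominator of the third rule uses
**post-integration** membership: a merged unit pools all its members'
transcripts, and a novel locus is its own denominator; the denominator sums
over all samples jointly. A zero gene total defines the fraction as 1
(0/0 := 1 — the transcript is all of nothing, and rules 1–2 already
eliminate all-zero rows). Transcripts excluded before this stage
(junction-failed candidates, exact matches) map to themselves in the
denominator so they cannot deflate a surviving sibling's gene fraction.

Monotonicity holds for every threshold (tightening never enlarges the kept
or passing set) and is property-tested.

## Summary and BUSCO conventions

Reported statistics round **half-up** at the stated precision: one decimal
for transcripts-per-gene, two decimals for percentages, integers for mean
and median lengths (the median of an even count is the mean of the central
pair, then rounded). Gene-level BUSCO reconciliation collapses isoform
multiplicity: per ortholog, hits on one gene → complete-single, on two or
more genes → complete-duplicated, fragmented only if no complete hit
exists, missing if the ortholog was never hit. Hit parsing is a minimal
three-column table (`busco_id`, `transcript_id`, `status`); full-table
dialects should be adapted upstream, though `Duplicated` rows are accepted
as complete hits and `Missing` rows are skipped.

## The synthetic data generator

`txrefine.fixtures` generates the entire test substrate from a seed: a
soft-masked toy genome, a multi-isoform reference annotation, candidate
transcripts planted per category, a junction-evidence table supporting
every planted novel junction, and an expression matrix in which each
filterable candidate violates exactly its planted rule.

Construction guarantees, which the tests then re-verify through the actual
code paths: reference isoforms of a gene use contiguous runs of the gene's
exon slots, while planted novel isoforms skip one interior slot, so the
skip junction exists nowhere in the reference and the chain can match no
reference isoform. Join candidates touch one exon of each of *k*
consecutive same-strand genes; *k* is drawn from a configurable
distribution whose default weights follow the 2..7 cardinality mix observed
in real refinement runs. Antisense candidates copy a reference isoform on
the opposite strand and are labelled `novel_gene` in truth (what a
strand-aware classifier must say) with a separate audit tag. Expression
plants use small integer totals placed with explicit margins around each
threshold so float arithmetic cannot blur a strict inequality; sibling
reference transcripts of a planted gene get budgets that keep the other two
rules clear of their boundaries. Defaults: 21 samples, three scaffolds,
~20 % soft-masking, 1–3 isoforms per gene, 2–5 exons per transcript.

What the generator does **not** emulate — and hence what green tests do not
show about real data: read-level noise (evidence tables are generated
directly, not derived from alignments), overlapping gene models on the same
strand, alternative transcription starts/ends within shared intron chains,
fractional expected counts, genome-scale repeat structure (masking is
periodic, not biological), and scaffold-boundary artefacts. The tests
demonstrate algorithmic correctness against planted truth and brute-force
oracles, not robustness to alignment noise.

## Problem sizes and determinism

Oracle-equivalence checks run at 500 candidates (classification, quadratic
per-base oracle), 1,000 random join sets (merge, BFS oracle) and ≥ 200
planted transcripts (expression filter); the end-to-end acceptance run uses
120 candidates over four scaffolds. These sizes exercise every category —
including join cardinalities up to seven — while the whole suite stays in
the tens of seconds. All randomness flows through explicit seeds
(`random.Random(seed)`; hypothesis runs derandomised), and every writer
emits in a total order, so identical inputs give byte-identical artifacts.

## Known limitations

* Gene records with zero transcripts are dropped on read (nothing anchors a
  span); standalone tRNA-style gene lines survive only if they carry
  transcript/exon records.
* The writer does not preserve the input's `source`/score columns on core
  features (pass-through features keep theirs); round-trip identity is at
  the model level, not byte level, for foreign files.
* No gene splitting: evidence that one annotated gene is really two is out
  of scope, only merges are performed.
* `softmask_fraction` requires in-memory sequences (a dict or an
  `pyfaidx`-style mapping); no windowed FASTA streaming.
* The merge step trusts classification: it does not re-check that joined
  genes share splice junctions across the boundary, though the
  classification record retains enough information for a stricter
  downstream policy.
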