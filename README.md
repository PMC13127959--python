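# txrefine

Reference-guided transcriptome annotation refinement.

Draft genome annotations — especially for non-model organisms — routinely
miss genes and isoforms that only appear in deeply sequenced, specialised
tissues. `txrefine` takes a reference annotation (GTF) and a set of
empirically assembled candidate transcripts (StringTie-style GTF with
coverage attributes) and produces an updated annotation, filtering the
candidates on the way in and reporting what changed. It is aimed at people
maintaining genome annotations for emerging model organisms from bulk or
single-cell RNA-seq evidence.

## What it does

Each candidate transcript is classified against the reference by same-strand
**exonic** overlap (span overlap would spuriously absorb intronic
transcripts) into a four-way partition:

| overlapping genes | intron chain | category |
|---|---|---|
| 1 | identical to a reference isoform | `exact_match` (dropped — nothing new) |
| 1 | different | `novel_isoform` (added to the gene, which keeps its name) |
| ≥ 2 | — | `join_evidence` (the loci form one transcription unit) |
| 0 | — | `novel_gene` |

Single-exon transcripts have no intron chain, so structural identity is
instead ≥ 80 % reciprocal exonic overlap with a single-exon reference
isoform. Join evidence is closed transitively: genes are nodes, spanning
transcripts contribute edges, and every connected component becomes one
merged gene under a fresh zero-padded identifier (`GBIG_G_000042`), its
members recorded in a `merged_from` attribute and its original transcript
identifiers retained. Novel transcripts are clustered into loci by
transitive exonic overlap and renamed `<gene_id>.t<n>`.

Two evidence filters gate the candidates:

* **junction support** — every splice junction not already in the reference
  needs ≥ 4 spliced reads with ≥ 15 bp anchors (defaults), and transcripts
  carrying a coverage estimate need coverage ≥ 10;
* **expression support** — a novel transcript is eliminated if it has
  assigned expression in < 30 % of samples, or < 10 reads summed over all
  samples, or < 10 % of the reads assigned to its (post-merge) gene. All
  three bounds are strict: exactly 10 reads or exactly 30 % passes.

QC reporting includes assembly summary statistics (gene/transcript counts,
spliced-length statistics), the merge-cardinality histogram, the fraction of
soft-masked (lowercase) sequence per transcript as a repeat-contamination
signal, and gene-level reconciliation of transcript-level BUSCO hits (an
ortholog hit by several isoforms of one gene counts once; "duplicated"
requires two distinct genes).

## Worked example

Everything below runs on synthetic data generated by the package itself:

```bash
refine make-fixture --seed 7 --out fixture/
refine run --reference fixture/reference.gtf --candidates fixture/candidates.gtf \
    --expression fixture/expression.tsv --junctions fixture/junctions.tsv \
    --genome fixture/genome.fa --outdir out/
```

prints the per-stage ledger:

```
candidates_in: 40
classified_exact_match: 8
classified_join_evidence: 6
classified_novel_gene: 16
classified_novel_isoform: 10
expression_kept: 17
expression_removed: 15
final_genes: 44
final_transcripts: 89
isoforms_added: 5
junction_fail: 0
junction_pass: 40
merge_components: 4
novel_genes: 8
reference_genes: 40
reference_transcripts: 72
```

Read it as: all 40 candidates clear the junction filter (the generator
supports every planted novel junction); 8 are structures the reference
already has and contribute nothing; the expression filter removes 15 of the
32 novel candidates (the generator plants rule violations); the 5 surviving
novel isoforms attach to their genes, 4 merge components fuse 8 reference
genes into 4, and 8 novel gene loci are created — hence
40 − 8 + 4 + 8 = 44 final genes and 72 + 17 = 89 transcripts.
`out/` contains `updated.gtf`, `classified.tsv`, `merges.tsv`,
`filter_report.tsv`, `provenance.tsv` and a human-readable `summary.txt`.

Subcommands (`refine classify`, `junction-filter`, `expr-filter`,
`integrate`, `summarize`, `busco-reconcile`, `make-fixture`) expose the
individual stages; the same functionality is importable from `txrefine`.

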