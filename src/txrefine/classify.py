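"""Four-way structural classification of candidate transcripts.

Each candidate is compared against the reference annotation and placed in
exactly one category, driven by the number of reference genes it shares
exonic sequence with on the same strand:

* 0 genes  -> ``novel_gene`` (includes purely intronic and antisense cases)
* 1 gene   -> ``exact_match`` if a reference isoform of that gene has an
  identical intron chain (single-exon candidates instead need >=80%
  reciprocal exonic overlap with a single-exon isoform); else
  ``novel_isoform``
* >=2 genes -> ``join_evidence`` (the transcript ties neighbouring gene
  loci into one transcription unit)

Overlap is exon-level, never span-level, so a transcript inside an intron
links to nothing.  Unstranded candidates match genes on either strand; when
that produces hits on both strands the gene with the largest exonic overlap
wins (ties to the smaller gene start).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import IO, Iterable

from .model import Annotation, Transcript, intron_chain, transcript_length


class ComparisonCode(str, enum.Enum):
    EXACT_MATCH = "exact_match"
    NOVEL_ISOFORM = "novel_isoform"
    JOIN_EVIDENCE = "join_evidence"
    NOVEL_GENE = "novel_gene"


@dataclass(frozen=True)
class ClassifiedTranscript:
    transcript_id: str
    code: ComparisonCode
    overlapping_gene_ids: tuple[str, ...]  # genomic order
    matched_reference_transcript: str | None = None

    def __post_init__(self) -> None:
        n = len(self.overlapping_gene_ids)
        expected = {
            ComparisonCode.NOVEL_GENE: n == 0,
            ComparisonCode.EXACT_MATCH: n == 1,
            ComparisonCode.NOVEL_ISOFORM: n == 1,
            ComparisonCode.JOIN_EVIDENCE: n >= 2,
        }
        if not expected[self.code]:
            raise ValueError(
                f"{self.transcript_id}: code {self.code.value} inconsistent with "
                f"{n} overlapping genes"
            )


def _merged_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(pairs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_bases(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    total, i, j = 0, 0, 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _gene_exonic_overlap(cand: Transcript, ref: Annotation, gene_id: str) -> int:
    """Bases shared between the candidate's exons and the union of the gene's exons."""
    cand_iv = _merged_intervals((e.interval.start, e.interval.end) for e in cand.exons)
    gene_iv = _merged_intervals(
        (e.interval.start, e.interval.end)
        for tid in ref.genes[gene_id].transcript_ids
        for e in ref.transcripts[tid].exons
        if e.interval.seqid == cand.seqid
    )
    return _overlap_bases(cand_iv, gene_iv)


def classify_transcript(
    cand: Transcript,
    ref: Annotation,
    single_exon_reciprocal_overlap: float = 0.80,
) -> ClassifiedTranscript:
    # genes whose exons overlap the candidate's exons, with strand agreement
    hit_genes: set[str] = set()
    for e in cand.exons:
        for tid in ref.overlapping_exon_transcripts(
            cand.seqid, e.interval.start, e.interval.end
        ):
            rt = ref.transcripts[tid]
            if cand.strand == "." or rt.strand == "." or rt.strand == cand.strand:
                # confirm the overlap is exonic, not just span-level (index is exon-level
                # already, so any hit qualifies)
                hit_genes.add(rt.gene_id)

    if cand.strand == ".":
        strands = {ref.transcripts[next(iter(ref.genes[g].transcript_ids))].strand
                   for g in hit_genes}
        if len(strands) > 1:
            # overlap on both strands: keep only the best-overlapping gene
            best = min(
                hit_genes,
                key=lambda g: (
                    -_gene_exonic_overlap(cand, ref, g),
                    ref.genes[g].span.start,
                    g,
                ),
            )
            hit_genes = {best}

    ordered = tuple(
        sorted(hit_genes, key=lambda g: (ref.genes[g].span.start, g))
    )

    if not ordered:
        return ClassifiedTranscript(cand.id, ComparisonCode.NOVEL_GENE, ())
    if len(ordered) >= 2:
        return ClassifiedTranscript(cand.id, ComparisonCode.JOIN_EVIDENCE, ordered)

    gene_id = ordered[0]
    cand_chain = intron_chain(cand)
    matched = None
    for tid in sorted(ref.genes[gene_id].transcript_ids):
        rt = ref.transcripts[tid]
        if cand_chain:
            if intron_chain(rt) == cand_chain:
                matched = tid
                break
        else:
            if len(rt.exons) != 1:
                continue
            ov = _gene_overlap_single(cand, rt)
            if (
                ov >= single_exon_reciprocal_overlap * transcript_length(cand)
                and ov >= single_exon_reciprocal_overlap * transcript_length(rt)
            ):
                matched = tid
                break
    if matched is not None:
        return ClassifiedTranscript(
            cand.id, ComparisonCode.EXACT_MATCH, ordered, matched
        )
    return ClassifiedTranscript(cand.id, ComparisonCode.NOVEL_ISOFORM, ordered)


def _gene_overlap_single(cand: Transcript, rt: Transcript) -> int:
    a = cand.exons[0].interval
    b = rt.exons[0].interval
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def classify_all(
    cands: Annotation,
    ref: Annotation,
    single_exon_reciprocal_overlap: float = 0.80,
) -> list[ClassifiedTranscript]:
    """Classify every candidate, in deterministic genomic order."""
    return [
        classify_transcript(
            cands.transcripts[tid], ref, single_exon_reciprocal_overlap
        )
        for tid in cands.sorted_transcript_ids()
    ]


def write_classification_table(
    classified: Iterable[ClassifiedTranscript], dest: IO[str]
) -> None:
    dest.write(
        "transcript_id\tcode\toverlapping_gene_ids\tmatched_reference_transcript\n"
    )
    for c in classified:
        dest.write(
            f"{c.transcript_id}\t{c.code.value}\t"
            f"{','.join(c.overlapping_gene_ids)}\t"
            f"{c.matched_reference_transcript or ''}\n"
        )
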