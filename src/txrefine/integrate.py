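"""Fuse surviving candidate transcripts into the reference annotation.

The integration contract:

* exact matches contribute nothing (the structure already exists);
* novel isoforms are attached to their single overlapping gene, which keeps
  its identifier and attributes;
* each merge component becomes one gene under a fresh identifier; the member
  genes' transcripts keep their original transcript ids and the spanning
  evidence transcripts join them; the retired gene ids are recorded;
* novel transcripts that overlap no reference gene are clustered into fresh
  gene loci (same-strand exonic overlap, transitive) and renamed
  ``<gene_id>.t<n>`` in genomic order;
* gene spans are recomputed and reference attributes carried over.

Fresh identifiers follow the ``GBIG_G_######`` convention: a configurable
prefix plus a zero-padded serial, assigned in genomic order (merge
components first, then novel loci) so the output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

from .classify import ClassifiedTranscript, ComparisonCode
from .errors import ConsistencyError, CoordinateError, DuplicateIdError
from .model import Annotation, Exon, GenomicInterval, Transcript, transcript_length


@dataclass
class IdentifierScheme:
    gene_prefix: str = "GBIG_G_"
    pad_width: int = 6
    next_serial: int = 1

    def next_id(self, taken: set[str]) -> str:
        while True:
            candidate = f"{self.gene_prefix}{self.next_serial:0{self.pad_width}d}"
            self.next_serial += 1
            if candidate not in taken:
                return candidate


PROVENANCE = ("reference_retained", "isoform_added", "join_member", "novel")


@dataclass
class IntegrationResult:
    updated: Annotation
    provenance: dict[str, str] = field(default_factory=dict)  # transcript -> status
    id_map: dict[str, str] = field(default_factory=dict)  # old gene -> new gene

    def write_provenance(self, dest) -> None:
        dest.write("transcript_id\tstatus\told_gene_id\tnew_gene_id\n")
        for tid in sorted(self.provenance):
            status = self.provenance[tid]
            t = self.updated.transcripts[tid]
            # reconstruct the pre-merge gene for join members where known
            old = next(
                (o for o, n in self.id_map.items() if n == t.gene_id), t.gene_id
            ) if status == "join_member" else t.gene_id
            dest.write(f"{tid}\t{status}\t{old}\t{t.gene_id}\n")


def _exons_overlap(a: Transcript, b: Transcript) -> bool:
    if a.seqid != b.seqid:
        return False
    if a.strand != "." and b.strand != "." and a.strand != b.strand:
        return False
    for ea in a.exons:
        for eb in b.exons:
            if ea.interval.overlap_length(eb.interval) > 0:
                return True
    return False


def cluster_novel_transcripts(novel: list[Transcript]) -> list[list[Transcript]]:
    """Group novel transcripts into gene loci by transitive exonic overlap.

    Returns clusters in genomic order; within each cluster transcripts are
    ordered genomically as well.
    """
    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(t.id for t in novel)
    by_id = {t.id: t for t in novel}
    by_seq: dict[str, list[Transcript]] = {}
    for t in novel:
        by_seq.setdefault(t.seqid, []).append(t)
    for group in by_seq.values():
        group.sort(key=lambda t: (t.start, t.id))
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if b.start > a.end:
                    break
                if _exons_overlap(a, b):
                    graph.add_edge(a.id, b.id)
    clusters = [
        sorted((by_id[tid] for tid in comp), key=lambda t: (t.start, t.id))
        for comp in nx.connected_components(graph)
    ]
    clusters.sort(key=lambda c: (c[0].seqid, c[0].start, c[0].id))
    return clusters


def integrate(
    ref: Annotation,
    survivors: Iterable[ClassifiedTranscript],
    transcripts: Mapping[str, Transcript] | Annotation,
    components=(),
    scheme: IdentifierScheme | None = None,
) -> IntegrationResult:
    """Build the updated annotation from filtered, classified candidates.

    ``transcripts`` resolves each survivor's id to its Transcript (an
    Annotation works).  ``components`` are the merge components derived from
    the same classification batch.
    """
    if isinstance(transcripts, Annotation):
        transcripts = transcripts.transcripts
    scheme = scheme or IdentifierScheme()
    survivors = list(survivors)

    updated = ref.copy()
    result = IntegrationResult(updated=updated)
    for tid in updated.transcripts:
        result.provenance[tid] = "reference_retained"

    taken = set(updated.genes) | set(updated.transcripts)
    component_of: dict[str, "object"] = {}
    for comp in components:
        for g in comp.member_gene_ids:
            component_of[g] = comp

    # (c) merge components, in genomic order
    def comp_key(comp):
        spans = [ref.genes[g].span for g in comp.member_gene_ids]
        leftmost = min((s.seqid, s.start) for s in spans)
        return (*leftmost, min(comp.member_gene_ids))

    new_gene_of_comp: dict[frozenset, str] = {}
    for comp in sorted(components, key=comp_key):
        missing = [g for g in comp.member_gene_ids if g not in updated.genes]
        if missing:
            raise ConsistencyError(f"merge component names unknown genes: {missing}")
        new_gid = scheme.next_id(taken)
        taken.add(new_gid)
        new_gene_of_comp[comp.member_gene_ids] = new_gid
        merged_attrs: dict[str, str] = {}
        moved: list[Transcript] = []
        for old_gid in sorted(comp.member_gene_ids):
            gene = updated.genes[old_gid]
            for k, v in gene.attributes.items():
                merged_attrs.setdefault(k, v)
            moved.extend(updated.remove_gene(old_gid))
            result.id_map[old_gid] = new_gid
        merged_attrs["merged_from"] = ",".join(sorted(comp.member_gene_ids))
        for t in moved:
            nt = replace(t, gene_id=new_gid)
            updated.add_transcript(nt, gene_attributes=merged_attrs)
            result.provenance[t.id] = "join_member"

    # (a, b, and join evidence) classified survivors
    novel_transcripts: list[Transcript] = []
    for rec in sorted(survivors, key=lambda r: r.transcript_id):
        t = transcripts[rec.transcript_id]
        if rec.code is ComparisonCode.EXACT_MATCH:
            continue
        if rec.code is ComparisonCode.NOVEL_GENE:
            novel_transcripts.append(t)
            continue
        if rec.code is ComparisonCode.JOIN_EVIDENCE:
            comp = component_of.get(rec.overlapping_gene_ids[0])
            if comp is None or not set(rec.overlapping_gene_ids) <= set(
                comp.member_gene_ids
            ):
                raise ConsistencyError(
                    f"join survivor {rec.transcript_id} has no covering merge component"
                )
            new_gid = new_gene_of_comp[comp.member_gene_ids]
            if t.id in updated.transcripts:
                raise DuplicateIdError(f"evidence transcript id {t.id!r} already present")
            updated.add_transcript(replace(t, gene_id=new_gid))
            result.provenance[t.id] = "join_member"
            continue
        # novel isoform of a single gene
        gid = rec.overlapping_gene_ids[0]
        if gid not in updated.genes:
            comp = component_of.get(gid)
            if comp is not None:
                raise ConsistencyError(
                    f"isoform survivor {rec.transcript_id} references gene {gid} "
                    "consumed by a merge component it is not part of"
                )
            raise ConsistencyError(
                f"isoform survivor {rec.transcript_id} references unknown gene {gid}"
            )
        if t.id in updated.transcripts:
            raise DuplicateIdError(f"isoform transcript id {t.id!r} already present")
        updated.add_transcript(replace(t, gene_id=gid))
        result.provenance[t.id] = "isoform_added"

    # (d) novel loci, clustered and renamed, in genomic order
    for cluster in cluster_novel_transcripts(novel_transcripts):
        new_gid = scheme.next_id(taken)
        taken.add(new_gid)
        for n, t in enumerate(cluster, start=1):
            new_tid = f"{new_gid}.t{n}"
            if new_tid in updated.transcripts:
                raise DuplicateIdError(f"generated transcript id {new_tid!r} collides")
            updated.add_transcript(replace(t, id=new_tid, gene_id=new_gid))
            result.provenance[new_tid] = "novel"
            taken.add(new_tid)

    updated.recompute_spans()
    return result


# ---------------------------------------------------------------------------
# soft-mask QC
# ---------------------------------------------------------------------------


def softmask_fraction(t: Transcript, genome: Mapping[str, str]) -> float:
    """Fraction of the transcript's exonic bases that are soft-masked (lowercase).

    ``genome`` maps seqid to sequence (plain strings or pyfaidx records).
    """
    seq = genome[t.seqid]
    masked = 0
    for e in t.exons:
        if e.interval.end > len(seq):
            raise CoordinateError(
                f"exon {e.interval.start}-{e.interval.end} of {t.id} exceeds "
                f"{t.seqid} length {len(seq)}"
            )
        chunk = str(seq[e.interval.start - 1 : e.interval.end])
        masked += sum(1 for c in chunk if c.islower())
    return masked / transcript_length(t)
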