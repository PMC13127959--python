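"""Evidence-based fusion of neighbouring gene loci.

A spanning transcript that shares exonic sequence with two or more annotated
genes is evidence that those loci are components of a single transcription
unit.  Merging is transitive: genes are nodes, each join-evidence transcript
contributes edges among the genes it touches, and every connected component
of the resulting graph becomes one merged unit.  Transitivity matters
because a unit of, say, seven original loci need not be spanned by any
single transcript.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import IO, Iterable

import networkx as nx

from .classify import ClassifiedTranscript, ComparisonCode
from .errors import ContractError
from .model import Annotation


@dataclass(frozen=True)
class MergeComponent:
    new_gene_id: str  # empty until the integrator assigns an identifier
    member_gene_ids: frozenset[str]
    evidence_transcript_ids: frozenset[str]

    @property
    def cardinality(self) -> int:
        return len(self.member_gene_ids)


@dataclass(frozen=True)
class MergeDistribution:
    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def build_merge_components(
    classified: Iterable[ClassifiedTranscript],
    ref: Annotation | None = None,
) -> list[MergeComponent]:
    """Connected components over genes linked by join-evidence transcripts.

    Records whose code is not ``join_evidence`` are ignored.  When ``ref``
    is supplied, components are sorted by the genomic position of their
    leftmost member gene; otherwise by sorted member ids.
    """
    graph: nx.Graph = nx.Graph()
    evidence: dict[str, set[str]] = {}
    for rec in classified:
        if rec.code is not ComparisonCode.JOIN_EVIDENCE:
            continue
        genes = rec.overlapping_gene_ids
        if len(genes) < 2:
            raise ContractError(
                f"join record {rec.transcript_id} names {len(genes)} genes (need >=2)"
            )
        graph.add_nodes_from(genes)
        graph.add_edges_from(zip(genes, genes[1:]))
        for g in genes:
            evidence.setdefault(g, set()).add(rec.transcript_id)

    components = []
    for nodes in nx.connected_components(graph):
        members = frozenset(nodes)
        tx = frozenset(t for g in members for t in evidence.get(g, ()))
        components.append(
            MergeComponent(new_gene_id="", member_gene_ids=members,
                           evidence_transcript_ids=tx)
        )

    if ref is not None:
        def key(c: MergeComponent):
            spans = [ref.genes[g].span for g in c.member_gene_ids if g in ref.genes]
            if spans:
                leftmost = min((s.seqid, s.start) for s in spans)
                return (0, leftmost[0], leftmost[1], min(c.member_gene_ids))
            return (1, "", 0, min(c.member_gene_ids))
    else:
        def key(c: MergeComponent):
            return tuple(sorted(c.member_gene_ids))

    return sorted(components, key=key)


def merge_distribution(components: Iterable[MergeComponent]) -> MergeDistribution:
    """Histogram of component cardinalities (how many loci each unit fused)."""
    return MergeDistribution(counts=dict(Counter(c.cardinality for c in components)))


def write_merge_table(components: Iterable[MergeComponent], dest: IO[str]) -> None:
    dest.write("new_gene_id\tmember_gene_ids\tevidence_transcript_ids\tcardinality\n")
    for c in components:
        dest.write(
            f"{c.new_gene_id}\t{','.join(sorted(c.member_gene_ids))}\t"
            f"{','.join(sorted(c.evidence_transcript_ids))}\t{c.cardinality}\n"
        )
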