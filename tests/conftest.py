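import random

import pytest
from hypothesis import settings

from txrefine import fixtures

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

TOY_GTF = """\
# two genes, three transcripts, six exons
scafA\ttest\tgene\t100\t1000\t.\t+\t.\tgene_id "G1"; name "alpha";
scafA\ttest\ttranscript\t100\t1000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
scafA\ttest\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
scafA\ttest\texon\t400\t500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
scafA\ttest\texon\t800\t1000\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t1";
scafA\ttest\ttranscript\t100\t500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t2";
scafA\ttest\texon\t100\t200\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t2";
scafA\ttest\texon\t400\t500\t.\t+\t.\tgene_id "G1"; transcript_id "G1.t2";
scafB\ttest\ttranscript\t2000\t2400\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
scafB\ttest\texon\t2000\t2400\t.\t-\t.\tgene_id "G2"; transcript_id "G2.t1";
"""


@pytest.fixture
def toy_gtf_text():
    return TOY_GTF


@pytest.fixture(scope="session")
def default_bundle():
    """One medium fixture bundle shared by read-only tests."""
    return fixtures.generate(fixtures.FixtureConfig(seed=7))


@pytest.fixture
def rng():
    return random.Random(20240917)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def exon_positions(transcript):
    """Set of genomic positions covered by a transcript's exons."""
    pos = set()
    for e in transcript.exons:
        pos.update(range(e.interval.start, e.interval.end + 1))
    return pos


def oracle_classify(cand, ref, reciprocal=0.80):
    """Quadratic exon-pair brute-force classifier, independent of the package.

    Tests every (candidate exon x reference exon) pair with per-base
    position sets, then applies the cardinality rules directly.
    """
    cand_pos = exon_positions(cand)
    overlap_by_gene = {}
    gene_strand = {}
    for rt in ref.transcripts.values():
        if rt.seqid != cand.seqid:
            continue
        gene_strand[rt.gene_id] = rt.strand
        if cand.strand != "." and rt.strand != "." and rt.strand != cand.strand:
            continue
        shared = cand_pos & exon_positions(rt)
        if shared:
            overlap_by_gene.setdefault(rt.gene_id, set()).update(shared)

    genes = set(overlap_by_gene)
    if cand.strand == "." and len({gene_strand[g] for g in genes}) > 1:
        genes = {
            min(genes, key=lambda g: (-len(overlap_by_gene[g]),
                                      ref.genes[g].span.start, g))
        }
    if not genes:
        return "novel_gene", ()
    ordered = tuple(sorted(genes, key=lambda g: (ref.genes[g].span.start, g)))
    if len(ordered) >= 2:
        return "join_evidence", ordered

    gene = ordered[0]

    def chain(t):
        ivs = sorted((e.interval.start, e.interval.end) for e in t.exons)
        return [(ivs[i][1], ivs[i + 1][0]) for i in range(len(ivs) - 1)]

    for tid in sorted(ref.genes[gene].transcript_ids):
        rt = ref.transcripts[tid]
        if len(cand.exons) > 1:
            if chain(rt) == chain(cand):
                return "exact_match", ordered
        elif len(rt.exons) == 1:
            shared = len(cand_pos & exon_positions(rt))
            if (shared >= reciprocal * len(cand_pos)
                    and shared >= reciprocal * len(exon_positions(rt))):
                return "exact_match", ordered
    return "novel_isoform", ordered


def oracle_components(edges_by_transcript):
    """BFS connected components over an explicitly built adjacency map."""
    adj = {}
    for genes in edges_by_transcript.values():
        for a, b in zip(genes, genes[1:]):
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        for g in genes:
            adj.setdefault(g, set())
    seen, components = set(), []
    for start in sorted(adj):
        if start in seen:
            continue
        queue, comp = [start], set()
        while queue:
            node = queue.pop()
            if node in comp:
                continue
            comp.add(node)
            queue.extend(adj[node] - comp)
        seen |= comp
        components.append(frozenset(comp))
    return set(components)
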