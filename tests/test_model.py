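"""Annotation model, GTF round trips, and interval-index correctness."""

import io
import random

import pytest

from txrefine import fixtures
from txrefine.errors import CoordinateError, DuplicateIdError, GtfParseError
from txrefine.model import (Annotation, Exon, GenomicInterval, Transcript,
                            intron_chain, read_gtf, transcript_length, write_gtf)

from conftest import exon_positions


def _tx(tid, gene, exon_coords, seqid="s1", strand="+"):
    exons = [Exon(GenomicInterval(seqid, s, e, strand), i + 1)
             for i, (s, e) in enumerate(exon_coords)]
    return Transcript(id=tid, gene_id=gene, exons=exons)


class TestReadGtf:
    def test_empty_stream(self):
        ann = read_gtf(io.StringIO(""))
        assert len(ann.genes) == 0 and len(ann.transcripts) == 0

    def test_toy_counts_and_mapping(self, toy_gtf_text):
        ann = read_gtf(toy_gtf_text)
        assert len(ann.genes) == 2
        assert len(ann.transcripts) == 3
        assert sum(len(t.exons) for t in ann.transcripts.values()) == 6
        assert ann.genes["G1"].transcript_ids == {"G1.t1", "G1.t2"}
        assert ann.genes["G2"].transcript_ids == {"G2.t1"}
        # explicit gene record attributes are preserved
        assert ann.genes["G1"].attributes == {"name": "alpha"}
        # G2 has no explicit gene record and is synthesized
        assert ann.genes["G2"].span.start == 2000

    def test_candidate_dialect_lifts_cov(self):
        gtf = (
            's1\tst\ttranscript\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t"; cov "12.5";\n'
            's1\tst\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        assert read_gtf(gtf, "candidate").transcripts["t"].coverage == 12.5
        ref = read_gtf(gtf, "reference")
        assert ref.transcripts["t"].coverage is None
        assert ref.transcripts["t"].attributes["cov"] == "12.5"

    def test_gff3_style_attributes_accepted(self):
        gtf = "s1\tx\texon\t5\t50\t.\t-\t.\tgene_id=g1;transcript_id=t1\n"
        ann = read_gtf(gtf)
        assert ann.transcripts["t1"].gene_id == "g1"

    @pytest.mark.parametrize(
        "line,exc",
        [
            ("s1\tx\texon\t5\t50\t.\t+\t.", GtfParseError),  # 8 columns
            ('s1\tx\texon\t50\t5\t.\t+\t.\tgene_id "g"; transcript_id "t";',
             CoordinateError),
        ],
    )
    def test_malformed_lines(self, line, exc):
        with pytest.raises(exc, match="line 1" if exc is GtfParseError else "end"):
            read_gtf(line + "\n")

    def test_duplicate_transcript_id(self):
        gtf = (
            's1\tx\ttranscript\t1\t9\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            's1\tx\texon\t1\t9\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            's1\tx\ttranscript\t20\t29\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(DuplicateIdError):
            read_gtf(gtf)

    def test_extra_features_pass_through(self):
        gtf = (
            's1\tx\ttranscript\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            's1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            's1\tx\tCDS\t10\t90\t.\t+\t0\tgene_id "g"; transcript_id "t"; tag "x";\n'
        )
        ann = read_gtf(gtf)
        (cds,) = ann.transcripts["t"].extra_features
        assert cds.feature_type == "CDS" and cds.frame == "0"
        assert dict(cds.attributes) == {"tag": "x"}
        # survives a write/read cycle
        again = read_gtf(write_gtf(ann))
        assert again.transcripts["t"].extra_features == (cds,)


class TestRoundTrip:
    def test_toy_round_trip_identity(self, toy_gtf_text):
        first = read_gtf(toy_gtf_text)
        second = read_gtf(write_gtf(first))
        assert second == first

    def test_write_deterministic(self, default_bundle):
        ann = default_bundle.reference
        assert write_gtf(ann) == write_gtf(ann)

    def test_bundle_round_trip(self, default_bundle):
        for ann, dialect in [(default_bundle.reference, "reference"),
                             (default_bundle.candidates, "candidate")]:
            assert read_gtf(write_gtf(ann), dialect) == ann

    def test_empty_annotation_writes_empty(self):
        assert write_gtf(Annotation()) == ""


class TestLengthAndChain:
    def test_single_exon_closed_arithmetic(self):
        assert transcript_length(_tx("t", "g", [(101, 200)])) == 100

    def test_two_exons(self):
        assert transcript_length(_tx("t", "g", [(1, 100), (201, 250)])) == 150

    def test_length_matches_position_set_oracle(self, default_bundle):
        for t in default_bundle.reference.transcripts.values():
            assert transcript_length(t) == len(exon_positions(t))

    def test_intron_chain_single_exon_empty(self):
        assert intron_chain(_tx("t", "g", [(1, 100)])) == []

    def test_intron_chain_three_exons(self):
        t = _tx("t", "g", [(1, 100), (201, 300), (401, 500)])
        assert intron_chain(t) == [(100, 201), (300, 401)]

    def test_length_at_least_exon_count(self, default_bundle):
        for t in default_bundle.candidates.transcripts.values():
            assert transcript_length(t) >= len(t.exons)
            span = t.end - t.start + 1
            if len(t.exons) == 1:
                assert transcript_length(t) == span
            else:
                assert transcript_length(t) < span


class TestIndex:
    def test_index_agrees_with_exhaustive_scan(self, default_bundle, rng):
        ann = default_bundle.reference
        seqids = sorted({t.seqid for t in ann.transcripts.values()})
        for _ in range(1000):
            seqid = rng.choice(seqids)
            start = rng.randint(1, 60_000)
            end = start + rng.randint(0, 3000)
            hits = ann.overlapping_exon_transcripts(seqid, start, end)
            brute = {
                t.id
                for t in ann.transcripts.values()
                if t.seqid == seqid
                and any(e.interval.start <= end and e.interval.end >= start
                        for e in t.exons)
            }
            assert hits == brute

    def test_gene_span_index(self, default_bundle, rng):
        ann = default_bundle.reference
        for _ in range(200):
            start = rng.randint(1, 60_000)
            end = start + rng.randint(0, 5000)
            hits = ann.overlapping_gene_spans("scaf01", start, end)
            brute = {
                g.id for g in ann.genes.values()
                if g.span.seqid == "scaf01"
                and g.span.start <= end and g.span.end >= start
            }
            assert hits == brute
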