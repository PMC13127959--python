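"""Integration of survivors into the reference: conservation, ids, soft-mask QC."""

import random

import pytest

from txrefine import fixtures
from txrefine.classify import (ClassifiedTranscript, ComparisonCode, classify_all)
from txrefine.errors import ConsistencyError, CoordinateError
from txrefine.integrate import (IdentifierScheme, cluster_novel_transcripts,
                                integrate, softmask_fraction)
from txrefine.merge import build_merge_components
from txrefine.model import (Annotation, Exon, GenomicInterval, Transcript,
                            write_gtf)

from conftest import exon_positions


def _tx(tid, exon_coords, strand="+", seqid="s1", gene=None, source="candidate"):
    exons = [Exon(GenomicInterval(seqid, s, e, strand), i + 1)
             for i, (s, e) in enumerate(exon_coords)]
    return Transcript(id=tid, gene_id=gene or f"g.{tid}", exons=exons, source=source)


def _integrated(bundle):
    classified = classify_all(bundle.candidates, bundle.reference)
    components = build_merge_components(classified, bundle.reference)
    result = integrate(bundle.reference, classified, bundle.candidates, components)
    return classified, components, result


class TestBasics:
    def test_no_survivors_is_identity(self, default_bundle):
        ref = default_bundle.reference
        result = integrate(ref, [], {}, [])
        assert result.updated == ref
        assert set(result.provenance.values()) == {"reference_retained"}

    def test_single_novel_gene_gets_serial_one(self):
        ref = Annotation()
        cand = _tx("STRG.1.1", [(100, 400)])
        rec = ClassifiedTranscript("STRG.1.1", ComparisonCode.NOVEL_GENE, ())
        result = integrate(ref, [rec], {"STRG.1.1": cand}, [])
        assert set(result.updated.genes) == {"GBIG_G_000001"}
        assert set(result.updated.transcripts) == {"GBIG_G_000001.t1"}
        assert result.provenance["GBIG_G_000001.t1"] == "novel"

    def test_exact_match_contributes_nothing(self, default_bundle):
        ref = default_bundle.reference
        exacts = [
            ClassifiedTranscript(t, ComparisonCode.EXACT_MATCH,
                                 (rec.host_gene,), rec.matched_transcript)
            for t, rec in default_bundle.truth.items()
            if rec.category == "exact_match"
        ]
        result = integrate(ref, exacts, default_bundle.candidates, [])
        assert result.updated == ref

    def test_isoform_into_consumed_gene_is_consistency_error(self):
        ref = Annotation()
        ref.add_transcript(_tx("A.t1", [(1, 100)], gene="A", source="reference"))
        ref.add_transcript(_tx("B.t1", [(500, 600)], gene="B", source="reference"))
        join = ClassifiedTranscript("j1", ComparisonCode.JOIN_EVIDENCE, ("A", "B"))
        comp = build_merge_components([join], ref)
        iso = ClassifiedTranscript("i1", ComparisonCode.NOVEL_ISOFORM, ("A",))
        txs = {"j1": _tx("j1", [(50, 120), (500, 550)]),
               "i1": _tx("i1", [(1, 80)])}
        with pytest.raises(ConsistencyError, match="consumed"):
            integrate(ref, [iso], txs, comp)


class TestFixtureArithmetic:
    def test_gene_and_transcript_accounting(self, default_bundle):
        b = default_bundle
        classified, components, result = _integrated(b)
        n_members = sum(len(c.member_gene_ids) for c in components)
        novel = [b.candidates.transcripts[c.transcript_id]
                 for c in classified if c.code is ComparisonCode.NOVEL_GENE]
        n_novel_genes = len(cluster_novel_transcripts(novel))
        assert len(result.updated.genes) == (
            len(b.reference.genes) - n_members + len(components) + n_novel_genes
        )
        n_added = sum(1 for c in classified
                      if c.code is not ComparisonCode.EXACT_MATCH)
        assert len(result.updated.transcripts) == (
            len(b.reference.transcripts) + n_added
        )

    def test_reference_transcripts_survive_exactly_once(self, default_bundle):
        b = default_bundle
        _, _, result = _integrated(b)
        for tid in b.reference.transcripts:
            assert tid in result.updated.transcripts
        # merged members moved under the fresh gene id
        for old, new in result.id_map.items():
            assert old not in result.updated.genes
            assert new in result.updated.genes
            assert result.updated.genes[new].attributes["merged_from"].count(old) == 1

    def test_no_dangling_references(self, default_bundle):
        _, _, result = _integrated(default_bundle)
        for t in result.updated.transcripts.values():
            assert t.gene_id in result.updated.genes
            assert t.id in result.updated.genes[t.gene_id].transcript_ids
        for g in result.updated.genes.values():
            spans = [result.updated.transcripts[t] for t in g.transcript_ids]
            assert g.span.start == min(t.start for t in spans)
            assert g.span.end == max(t.end for t in spans)

    def test_provenance_covers_everything(self, default_bundle):
        _, _, result = _integrated(default_bundle)
        assert set(result.provenance) == set(result.updated.transcripts)

    def test_deterministic_output_bytes(self, default_bundle):
        _, _, r1 = _integrated(default_bundle)
        _, _, r2 = _integrated(default_bundle)
        assert write_gtf(r1.updated) == write_gtf(r2.updated)

    def test_idempotent_reintegration(self, default_bundle):
        _, _, result = _integrated(default_bundle)
        again = integrate(result.updated, [], {}, [])
        assert again.updated == result.updated
        assert again.id_map == {}


class TestNovelClustering:
    def test_overlapping_novels_share_one_gene(self):
        ref = Annotation()
        a = _tx("n1", [(100, 300)])
        b = _tx("n2", [(250, 500)])
        c = _tx("n3", [(5000, 5200)])
        recs = [ClassifiedTranscript(t.id, ComparisonCode.NOVEL_GENE, ())
                for t in (a, b, c)]
        result = integrate(ref, recs, {t.id: t for t in (a, b, c)}, [])
        assert len(result.updated.genes) == 2
        g1 = result.updated.genes["GBIG_G_000001"]
        assert g1.transcript_ids == {"GBIG_G_000001.t1", "GBIG_G_000001.t2"}
        assert result.updated.genes["GBIG_G_000002"].transcript_ids == {
            "GBIG_G_000002.t1"
        }

    def test_scheme_skips_taken_serials(self):
        ref = Annotation()
        ref.add_transcript(
            _tx("x.t1", [(9000, 9100)], gene="GBIG_G_000001", source="reference")
        )
        cand = _tx("n1", [(100, 200)])
        rec = ClassifiedTranscript("n1", ComparisonCode.NOVEL_GENE, ())
        result = integrate(ref, [rec], {"n1": cand}, [],
                           IdentifierScheme(next_serial=1))
        assert "GBIG_G_000002" in result.updated.genes


class TestSoftmask:
    def test_all_upper_and_all_lower(self):
        t = _tx("t", [(1, 10), (21, 30)])
        assert softmask_fraction(t, {"s1": "A" * 40}) == 0.0
        assert softmask_fraction(t, {"s1": "a" * 40}) == 1.0

    def test_out_of_bounds_exon(self):
        t = _tx("t", [(95, 120)])
        with pytest.raises(CoordinateError):
            softmask_fraction(t, {"s1": "A" * 100})

    def test_matches_per_base_oracle(self, default_bundle, rng):
        b = default_bundle
        picks = sorted(b.reference.transcripts)
        rng.shuffle(picks)
        for tid in picks[:25]:
            t = b.reference.transcripts[tid]
            seq = b.genome[t.seqid]
            brute = sum(1 for p in exon_positions(t) if seq[p - 1].islower())
            assert softmask_fraction(t, b.genome) == pytest.approx(
                brute / len(exon_positions(t))
            )
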