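"""Summary statistics, rounding conventions, and BUSCO gene-level reconciliation."""

import pytest

from txrefine.errors import ContractError, MappingError
from txrefine.model import Annotation, Exon, GenomicInterval, Transcript
from txrefine.summary import (BuscoTranscriptHit, assembly_summary,
                              busco_gene_reconcile, percentage, ratio_1dp,
                              read_busco_hits)


def _tx(tid, gene, exon_coords, seqid="s1"):
    exons = [Exon(GenomicInterval(seqid, s, e, "+"), i + 1)
             for i, (s, e) in enumerate(exon_coords)]
    return Transcript(id=tid, gene_id=gene, exons=exons)


class TestRatiosAndPercentages:
    @pytest.mark.parametrize(
        "n_tx,n_genes,expected",
        [(43394, 20533, 2.1), (28529, 17871, 1.6)],
    )
    def test_transcripts_per_gene_ratios(self, n_tx, n_genes, expected):
        assert ratio_1dp(n_tx, n_genes) == expected

    @pytest.mark.parametrize(
        "count,total,expected",
        [(1001, 1013, 98.82), (965, 1013, 95.26), (5, 1013, 0.49),
         (0, 1013, 0.00), (26, 1013, 2.57), (22, 1013, 2.17)],
    )
    def test_percentage_half_up_two_decimals(self, count, total, expected):
        assert percentage(count, total) == expected

    def test_half_up_not_bankers(self):
        assert percentage(1, 8) == 12.50
        assert percentage(25, 1000) == 2.50
        assert ratio_1dp(25, 100) == 0.3  # 0.25 rounds up, not to even

    def test_percentage_contract(self):
        with pytest.raises(ContractError):
            percentage(1, 0)
        with pytest.raises(ContractError):
            percentage(5, 4)


class TestAssemblySummary:
    def test_empty_annotation_all_zero(self):
        s = assembly_summary(Annotation())
        assert (s.n_genes, s.n_transcripts, s.mean_tx_per_gene) == (0, 0, 0.0)

    def test_five_gene_fixture_hand_computed(self):
        """Spliced lengths: 100, 150, 200, 301, 60; 2 genes have 2 isoforms."""
        ann = Annotation()
        ann.add_transcript(_tx("a.t1", "a", [(1, 100)]))               # 100
        ann.add_transcript(_tx("a.t2", "a", [(1, 50), (101, 200)]))    # 150
        ann.add_transcript(_tx("b.t1", "b", [(300, 499)]))             # 200
        ann.add_transcript(_tx("b.t2", "b", [(300, 600)]))             # 301
        ann.add_transcript(_tx("c.t1", "c", [(900, 959)]))             # 60
        s = assembly_summary(ann)
        assert s.n_genes == 3
        assert s.n_transcripts == 5
        assert s.mean_tx_per_gene == 1.7      # 5/3 = 1.666.. -> 1.7
        assert s.max_tx_per_gene == 2
        assert s.mean_tx_length == 162        # 811/5 = 162.2 -> 162
        assert s.median_tx_length == 150
        assert s.max_tx_length == 301

    def test_even_count_median_rounds_half_up(self):
        ann = Annotation()
        ann.add_transcript(_tx("a.t1", "a", [(1, 100)]))    # 100
        ann.add_transcript(_tx("b.t1", "b", [(1, 201)]))    # 201
        s = assembly_summary(ann)
        assert s.median_tx_length == 151  # (100+201)/2 = 150.5 -> 151


class TestBuscoReconcile:
    TX2GENE = {"g1.t1": "g1", "g1.t2": "g1", "g2.t1": "g2", "g3.t1": "g3"}

    def test_isoforms_of_one_gene_collapse_to_single(self):
        hits = [BuscoTranscriptHit("B1", "g1.t1", "complete"),
                BuscoTranscriptHit("B1", "g1.t2", "complete")]
        table = busco_gene_reconcile(hits, self.TX2GENE, 10)
        assert table.complete_single == 1
        assert table.complete_duplicated == 0

    def test_two_distinct_genes_is_duplicated(self):
        hits = [BuscoTranscriptHit("B1", "g1.t1", "complete"),
                BuscoTranscriptHit("B1", "g2.t1", "complete")]
        table = busco_gene_reconcile(hits, self.TX2GENE, 10)
        assert table.complete_duplicated == 1

    def test_complete_takes_precedence_over_fragmented(self):
        hits = [BuscoTranscriptHit("B1", "g1.t1", "fragmented"),
                BuscoTranscriptHit("B1", "g2.t1", "complete")]
        table = busco_gene_reconcile(hits, self.TX2GENE, 10)
        assert table.complete_single == 1 and table.fragmented == 0

    def test_all_five_categories_and_sums(self):
        hits = [
            BuscoTranscriptHit("B1", "g1.t1", "complete"),   # single
            BuscoTranscriptHit("B2", "g1.t1", "complete"),   # duplicated
            BuscoTranscriptHit("B2", "g2.t1", "complete"),
            BuscoTranscriptHit("B3", "g3.t1", "fragmented"),  # fragmented
        ]
        table = busco_gene_reconcile(hits, self.TX2GENE, 5)  # B4, B5 missing
        assert (table.complete_single, table.complete_duplicated,
                table.fragmented, table.missing) == (1, 1, 1, 2)
        assert table.complete_total == table.complete_single + table.complete_duplicated
        assert (table.complete_total + table.fragmented + table.missing
                == table.total_orthologs)

    def test_random_tables_match_per_ortholog_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        tx2gene = {f"{g}.t{j}": g for g in genes for j in (1, 2)}
        txs = sorted(tx2gene)
        for _ in range(50):
            hits = []
            for b in range(15):
                for _ in range(rng.randint(0, 4)):
                    hits.append(BuscoTranscriptHit(
                        f"B{b}", rng.choice(txs),
                        rng.choice(["complete", "fragmented"])
                    ))
            table = busco_gene_reconcile(hits, tx2gene, 15)
            # naive per-ortholog evaluation
            single = dup = frag = 0
            for b in range(15):
                cgenes = {tx2gene[h.transcript_id] for h in hits
                          if h.busco_id == f"B{b}" and h.status == "complete"}
                fgenes = {tx2gene[h.transcript_id] for h in hits
                          if h.busco_id == f"B{b}" and h.status == "fragmented"}
                if len(cgenes) == 1:
                    single += 1
                elif len(cgenes) >= 2:
                    dup += 1
                elif fgenes:
                    frag += 1
            assert (table.complete_single, table.complete_duplicated,
                    table.fragmented) == (single, dup, frag)

    def test_unknown_transcript_is_mapping_error(self):
        with pytest.raises(MappingError):
            busco_gene_reconcile(
                [BuscoTranscriptHit("B1", "nope", "complete")], self.TX2GENE, 5
            )

    def test_tabular_adapter(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "busco_id\ttranscript_id\tstatus\n"
            "B1\tg1.t1\tComplete\nB1\tg2.t1\tDuplicated\nB9\tg3.t1\tMissing\n"
        )
        hits = read_busco_hits(path)
        assert [h.status for h in hits] == ["complete", "complete"]
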