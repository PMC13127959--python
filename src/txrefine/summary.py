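"""Assembly summary statistics, merge accounting, and gene-level BUSCO tables.

Rounding follows the reporting conventions used throughout: half-up at the
stated precision — one decimal for transcripts-per-gene ratios, two decimals
for percentages, integers for mean/median transcript lengths.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import IO, Iterable, Mapping

from .errors import ContractError, MappingError
from .model import Annotation, transcript_length


def _half_up(value: Decimal, exponent: str) -> Decimal:
    return value.quantize(Decimal(exponent), rounding=ROUND_HALF_UP)


def ratio_1dp(numerator: int, denominator: int) -> float:
    """numerator/denominator rounded half-up to 1 decimal (e.g. 43394/20533 -> 2.1)."""
    if denominator <= 0:
        raise ContractError("denominator must be positive")
    return float(_half_up(Decimal(numerator) / Decimal(denominator), "0.1"))


def percentage(count: int, total: int) -> float:
    """100*count/total rounded half-up to 2 decimals."""
    if total <= 0:
        raise ContractError("total must be positive")
    if not 0 <= count <= total:
        raise ContractError("count must lie in [0, total]")
    return float(_half_up(Decimal(100 * count) / Decimal(total), "0.01"))


@dataclass(frozen=True)
class AssemblySummary:
    n_genes: int
    n_transcripts: int
    mean_tx_per_gene: float
    max_tx_per_gene: int
    mean_tx_length: int
    median_tx_length: int
    max_tx_length: int

    def as_text(self, label: str = "assembly") -> str:
        rows = [
            ("N(Genes)", f"{self.n_genes:,}"),
            ("N(Transcripts)", f"{self.n_transcripts:,}"),
            ("Average transcripts per gene", f"{self.mean_tx_per_gene}"),
            ("Max transcripts per gene", f"{self.max_tx_per_gene:,}"),
            ("Average transcript length", f"{self.mean_tx_length:,}"),
            ("Median transcript length", f"{self.median_tx_length:,}"),
            ("Max transcript length", f"{self.max_tx_length:,}"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = [f"[{label}]"] + [f"  {k:<{width}}  {v}" for k, v in rows]
        return "\n".join(lines)


def assembly_summary(ann: Annotation) -> AssemblySummary:
    """Gene/transcript counts and spliced-length statistics of one annotation."""
    if not ann.transcripts:
        return AssemblySummary(0, 0, 0.0, 0, 0, 0, 0)
    lengths = sorted(transcript_length(t) for t in ann.transcripts.values())
    n_tx, n_genes = len(lengths), len(ann.genes)
    mid = len(lengths) // 2
    if len(lengths) % 2:
        median = Decimal(lengths[mid])
    else:
        median = Decimal(lengths[mid - 1] + lengths[mid]) / 2
    return AssemblySummary(
        n_genes=n_genes,
        n_transcripts=n_tx,
        mean_tx_per_gene=ratio_1dp(n_tx, n_genes),
        max_tx_per_gene=max(len(g.transcript_ids) for g in ann.genes.values()),
        mean_tx_length=int(_half_up(Decimal(sum(lengths)) / n_tx, "1")),
        median_tx_length=int(_half_up(median, "1")),
        max_tx_length=lengths[-1],
    )


# ---------------------------------------------------------------------------
# gene-level BUSCO reconciliation
# ---------------------------------------------------------------------------

BUSCO_STATUSES = ("complete", "fragmented")


@dataclass(frozen=True)
class BuscoTranscriptHit:
    busco_id: str
    transcript_id: str
    status: str  # "complete" | "fragmented"

    def __post_init__(self) -> None:
        if self.status not in BUSCO_STATUSES:
            raise ContractError(
                f"hit status must be one of {BUSCO_STATUSES}, got {self.status!r}"
            )


@dataclass(frozen=True)
class BuscoGeneTable:
    total_orthologs: int
    complete_single: int
    complete_duplicated: int
    fragmented: int
    missing: int

    @property
    def complete_total(self) -> int:
        return self.complete_single + self.complete_duplicated

    def percent(self, category: str) -> float:
        return percentage(getattr(self, category) if category != "complete_total"
                          else self.complete_total, self.total_orthologs)

    def as_text(self) -> str:
        rows = [
            ("complete- total", self.complete_total),
            ("complete-single", self.complete_single),
            ("complete-duplicated", self.complete_duplicated),
            ("fragmented", self.fragmented),
            ("missing", self.missing),
        ]
        lines = ["category\tcount\tpercent"]
        for name, count in rows:
            lines.append(f"{name}\t{count}\t{percentage(count, self.total_orthologs):.2f}")
        lines.append(f"total\t{self.total_orthologs}\t")
        return "\n".join(lines)


def busco_gene_reconcile(
    hits: Iterable[BuscoTranscriptHit],
    tx_to_gene: Mapping[str, str],
    total_orthologs: int,
) -> BuscoGeneTable:
    """Collapse transcript-level BUSCO hits to gene level.

    Multiple isoforms of one gene hitting the same ortholog count once, so a
    'duplication' requires hits on at least two distinct genes.  Per
    ortholog: >=1 gene with a complete hit -> complete (single if one gene,
    duplicated if more); else >=1 fragmented hit -> fragmented; orthologs
    with no hits at all are missing.
    """
    complete_genes: dict[str, set[str]] = {}
    fragment_genes: dict[str, set[str]] = {}
    seen: set[str] = set()
    for hit in hits:
        if hit.transcript_id not in tx_to_gene:
            raise MappingError(
                f"BUSCO hit transcript {hit.transcript_id!r} has no gene mapping"
            )
        gene = tx_to_gene[hit.transcript_id]
        seen.add(hit.busco_id)
        bucket = complete_genes if hit.status == "complete" else fragment_genes
        bucket.setdefault(hit.busco_id, set()).add(gene)
    if total_orthologs < len(seen):
        raise ContractError(
            f"total_orthologs {total_orthologs} < {len(seen)} distinct observed ids"
        )

    single = duplicated = fragmented = 0
    for bid in seen:
        genes = complete_genes.get(bid, set())
        if len(genes) == 1:
            single += 1
        elif len(genes) >= 2:
            duplicated += 1
        else:
            fragmented += 1
    return BuscoGeneTable(
        total_orthologs=total_orthologs,
        complete_single=single,
        complete_duplicated=duplicated,
        fragmented=fragmented,
        missing=total_orthologs - len(seen),
    )


def read_busco_hits(source: str | Path | IO[str]) -> list[BuscoTranscriptHit]:
    """Minimal tabular adapter: columns busco_id, transcript_id, status.

    ``Complete``/``Duplicated`` statuses from full-table exports both count
    as complete hits (duplication is re-derived at gene level); ``Missing``
    rows are skipped.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_busco_hits(fh)
    hits = []
    reader = csv.DictReader(source, delimiter="\t")
    for row in reader:
        status = row["status"].strip().lower()
        if status == "duplicated":
            status = "complete"
        if status == "missing":
            continue
        hits.append(
            BuscoTranscriptHit(
                busco_id=row["busco_id"],
                transcript_id=row["transcript_id"],
                status=status,
            )
        )
    return hits


def merge_distribution_text(counts: Mapping[int, int]) -> str:
    lines = ["joined_neighbors\tinstances"]
    for k in sorted(counts):
        lines.append(f"{k}\t{counts[k]}")
    lines.append(f"total\t{sum(counts.values())}")
    return "\n".join(lines)
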