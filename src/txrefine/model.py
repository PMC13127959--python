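"""Genomic annotation data model with GTF I/O and interval indexing.

The model mirrors the gene -> transcript -> exon hierarchy of a GTF file.
Coordinates are stored in GTF convention throughout: 1-based, closed
intervals, so an exon spanning positions 101..200 has length 100.

Two reading dialects are supported: ``reference`` for a curated genome
annotation and ``candidate`` for assembler output (StringTie-style), where a
``cov`` attribute on the transcript line is lifted into
:attr:`Transcript.coverage`.  Features other than gene/transcript/exon (CDS,
UTR, start/stop codon...) are retained verbatim on their transcript and
re-emitted on write, never interpreted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

from intervaltree import IntervalTree

from .errors import CoordinateError, DuplicateIdError, GtfParseError

STRANDS = ("+", "-", ".")

_CORE_FEATURES = frozenset({"gene", "transcript", "exon"})

# `key "value";` (GTF2.2) -- value may contain anything but an unescaped quote
_GTF_ATTR = re.compile(r'\s*(\S+)\s+"([^"]*)"\s*')
# `key=value` (GFF3-ish)
_GFF_ATTR = re.compile(r"\s*([^=;\s]+)\s*=\s*([^;]*)\s*")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based closed interval on one scaffold."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise CoordinateError(f"start {self.start} < 1 on {self.seqid}")
        if self.end < self.start:
            raise CoordinateError(
                f"end {self.end} < start {self.start} on {self.seqid}"
            )
        if self.strand not in STRANDS:
            raise CoordinateError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    rank: int  # ordinal within the transcript, 5'->3' on genome coordinates


@dataclass(frozen=True)
class ExtraFeature:
    """A non-core GTF feature (CDS, UTR...) carried verbatim with its transcript."""

    feature_type: str
    interval: GenomicInterval
    score: str
    frame: str
    attributes: tuple[tuple[str, str], ...]


@dataclass
class Transcript:
    id: str
    gene_id: str
    exons: list[Exon]
    source: str = "reference"  # "reference" | "candidate"
    coverage: float | None = None
    attributes: dict[str, str] = field(default_factory=dict)
    extra_features: tuple[ExtraFeature, ...] = ()

    @property
    def seqid(self) -> str:
        return self.exons[0].interval.seqid

    @property
    def strand(self) -> str:
        return self.exons[0].interval.strand

    @property
    def start(self) -> int:
        return self.exons[0].interval.start

    @property
    def end(self) -> int:
        return self.exons[-1].interval.end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.seqid, self.start, self.end, self.strand)


@dataclass
class Gene:
    id: str
    transcript_ids: set[str]
    span: GenomicInterval
    attributes: dict[str, str] = field(default_factory=dict)


def transcript_length(t: Transcript) -> int:
    """Spliced (mature) length: sum of exon lengths, not the genomic span."""
    return sum(len(e.interval) for e in t.exons)


def intron_chain(t: Transcript) -> list[tuple[int, int]]:
    """Ordered (donor_end, acceptor_start) pairs; empty for single-exon."""
    return [
        (t.exons[i].interval.end, t.exons[i + 1].interval.start)
        for i in range(len(t.exons) - 1)
    ]


class Annotation:
    """A consistent set of genes and transcripts with interval indices.

    The index is built lazily on first query and dropped on mutation; all
    index queries agree with an exhaustive scan over the model (covered by
    the property tests).
    """

    def __init__(self) -> None:
        self.genes: dict[str, Gene] = {}
        self.transcripts: dict[str, Transcript] = {}
        self._exon_index: dict[str, IntervalTree] | None = None
        self._gene_index: dict[str, IntervalTree] | None = None

    # -- construction -----------------------------------------------------

    def add_transcript(self, t: Transcript, gene_attributes: dict | None = None) -> None:
        if t.id in self.transcripts:
            raise DuplicateIdError(f"duplicate transcript id {t.id!r}")
        if not t.exons:
            raise CoordinateError(f"transcript {t.id!r} has no exons")
        self.transcripts[t.id] = t
        gene = self.genes.get(t.gene_id)
        if gene is None:
            self.genes[t.gene_id] = Gene(
                id=t.gene_id,
                transcript_ids={t.id},
                span=t.span,
                attributes=dict(gene_attributes or {}),
            )
        else:
            gene.transcript_ids.add(t.id)
            if gene_attributes:
                gene.attributes.update(gene_attributes)
            self._recompute_span(gene)
        self._drop_index()

    def remove_gene(self, gene_id: str) -> list[Transcript]:
        """Remove a gene and all its transcripts; returns the removed transcripts."""
        gene = self.genes.pop(gene_id)
        removed = [self.transcripts.pop(tid) for tid in sorted(gene.transcript_ids)]
        self._drop_index()
        return removed

    def _recompute_span(self, gene: Gene) -> None:
        txs = [self.transcripts[tid] for tid in gene.transcript_ids]
        gene.span = GenomicInterval(
            txs[0].seqid,
            min(t.start for t in txs),
            max(t.end for t in txs),
            txs[0].strand,
        )

    def recompute_spans(self) -> None:
        for gene in self.genes.values():
            self._recompute_span(gene)
        self._drop_index()

    # -- index ------------------------------------------------------------

    def _drop_index(self) -> None:
        self._exon_index = None
        self._gene_index = None

    def _build_index(self) -> None:
        self._exon_index = {}
        self._gene_index = {}
        for t in self.transcripts.values():
            tree = self._exon_index.setdefault(t.seqid, IntervalTree())
            for e in t.exons:
                # half-open internally; public API stays 1-based closed
                tree.addi(e.interval.start, e.interval.end + 1, t.id)
        for g in self.genes.values():
            tree = self._gene_index.setdefault(g.span.seqid, IntervalTree())
            tree.addi(g.span.start, g.span.end + 1, g.id)

    def overlapping_exon_transcripts(self, seqid: str, start: int, end: int) -> set[str]:
        """Transcript ids with >=1 exon base overlapping [start, end] on seqid."""
        if self._exon_index is None:
            self._build_index()
        tree = self._exon_index.get(seqid)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}

    def overlapping_gene_spans(self, seqid: str, start: int, end: int) -> set[str]:
        if self._gene_index is None:
            self._build_index()
        tree = self._gene_index.get(seqid)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(start, end + 1)}

    # -- convenience ------------------------------------------------------

    def transcripts_of(self, gene_id: str) -> list[Transcript]:
        return [
            self.transcripts[tid] for tid in sorted(self.genes[gene_id].transcript_ids)
        ]

    def sorted_gene_ids(self) -> list[str]:
        return sorted(
            self.genes, key=lambda g: (self.genes[g].span.seqid, self.genes[g].span.start, g)
        )

    def sorted_transcript_ids(self) -> list[str]:
        return sorted(
            self.transcripts,
            key=lambda t: (
                self.transcripts[t].seqid,
                self.transcripts[t].start,
                t,
            ),
        )

    def copy(self) -> "Annotation":
        out = Annotation()
        for tid in self.transcripts:
            t = self.transcripts[tid]
            out.transcripts[tid] = replace(
                t, exons=list(t.exons), attributes=dict(t.attributes)
            )
        for gid, g in self.genes.items():
            out.genes[gid] = Gene(
                id=g.id,
                transcript_ids=set(g.transcript_ids),
                span=g.span,
                attributes=dict(g.attributes),
            )
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Annotation):
            return NotImplemented
        return self.genes == other.genes and self.transcripts == other.transcripts

    def __repr__(self) -> str:
        return f"<Annotation: {len(self.genes)} genes, {len(self.transcripts)} transcripts>"


# ---------------------------------------------------------------------------
# GTF reading
# ---------------------------------------------------------------------------


def _parse_attributes(raw: str, line_no: int) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        m = _GTF_ATTR.fullmatch(part)
        if m is None:
            m = _GFF_ATTR.fullmatch(part)
        if m is None:
            raise GtfParseError(f"line {line_no}: unparseable attribute {part!r}")
        attrs[m.group(1)] = m.group(2)
    return attrs


def _as_lines(source: str | Path | IO[str]) -> Iterator[str]:
    if isinstance(source, Path):
        yield from source.read_text().splitlines()
    elif isinstance(source, str):
        if "\t" in source or "\n" in source or not source:
            yield from source.splitlines()
        else:
            yield from Path(source).read_text().splitlines()
    else:
        for line in source:
            yield line.rstrip("\n")


def read_gtf(source: str | Path | IO[str], dialect: str = "reference") -> Annotation:
    """Parse GTF into an :class:`Annotation`.

    Genes absent as explicit records are synthesized from their transcripts'
    ``gene_id``.  In the ``candidate`` dialect a ``cov`` attribute becomes
    :attr:`Transcript.coverage`.
    """
    if dialect not in ("reference", "candidate"):
        raise ValueError(f"unknown dialect {dialect!r}")

    gene_attrs: dict[str, dict[str, str]] = {}
    tx_attrs: dict[str, dict[str, str]] = {}
    tx_gene: dict[str, str] = {}
    tx_cov: dict[str, float] = {}
    tx_exons: dict[str, list[GenomicInterval]] = {}
    tx_extra: dict[str, list[ExtraFeature]] = {}
    tx_order: list[str] = []

    for line_no, line in enumerate(_as_lines(source), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GtfParseError(
                f"line {line_no}: expected 9 tab-delimited columns, got {len(cols)}"
            )
        seqid, _src, feature, start_s, end_s, score, strand, frame, attr_raw = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise GtfParseError(f"line {line_no}: non-integer coordinates") from exc
        if end < start:
            raise CoordinateError(f"line {line_no}: end {end} < start {start}")
        if strand not in STRANDS:
            raise GtfParseError(f"line {line_no}: invalid strand {strand!r}")
        attrs = _parse_attributes(attr_raw, line_no)
        interval = GenomicInterval(seqid, start, end, strand)

        if feature == "gene":
            gid = attrs.get("gene_id")
            if gid is None:
                raise GtfParseError(f"line {line_no}: gene record lacks gene_id")
            a = dict(attrs)
            a.pop("gene_id", None)
            gene_attrs.setdefault(gid, {}).update(a)
            continue

        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id")
        if feature == "transcript":
            if tid is None or gid is None:
                raise GtfParseError(
                    f"line {line_no}: transcript record lacks gene_id/transcript_id"
                )
            if tid in tx_attrs:
                raise DuplicateIdError(f"line {line_no}: duplicate transcript id {tid!r}")
            a = dict(attrs)
            a.pop("gene_id", None)
            a.pop("transcript_id", None)
            if dialect == "candidate" and "cov" in a:
                tx_cov[tid] = float(a.pop("cov"))
            tx_attrs[tid] = a
            tx_gene[tid] = gid
            if tid not in tx_exons:
                tx_order.append(tid)
                tx_exons[tid] = []
        elif feature == "exon":
            if tid is None or gid is None:
                raise GtfParseError(
                    f"line {line_no}: exon record lacks gene_id/transcript_id"
                )
            if tid not in tx_exons:
                tx_order.append(tid)
                tx_exons[tid] = []
            tx_exons[tid].append(interval)
            tx_gene.setdefault(tid, gid)
        elif tid is not None:
            extras = tx_extra.setdefault(tid, [])
            extras.append(
                ExtraFeature(
                    feature_type=feature,
                    interval=interval,
                    score=score,
                    frame=frame,
                    attributes=tuple(
                        (k, v)
                        for k, v in attrs.items()
                        if k not in ("gene_id", "transcript_id")
                    ),
                )
            )
        # featureless-of-interest lines without transcript_id are ignored

    ann = Annotation()
    for tid in tx_order:
        intervals = tx_exons.get(tid, [])
        if not intervals:
            raise GtfParseError(f"transcript {tid!r} has no exon records")
        intervals.sort(key=lambda iv: iv.start)
        exons = [Exon(interval=iv, rank=i + 1) for i, iv in enumerate(intervals)]
        gid = tx_gene[tid]
        t = Transcript(
            id=tid,
            gene_id=gid,
            exons=exons,
            source=dialect,
            coverage=tx_cov.get(tid),
            attributes=tx_attrs.get(tid, {}),
            extra_features=tuple(
                sorted(
                    tx_extra.get(tid, ()),
                    key=lambda f: (f.feature_type, f.interval.start, f.interval.end),
                )
            ),
        )
        ann.add_transcript(t, gene_attributes=gene_attrs.get(gid))
    # gene records with no transcripts are dropped (nothing to anchor a span)
    return ann


# ---------------------------------------------------------------------------
# GTF writing
# ---------------------------------------------------------------------------


def _format_attrs(pairs: Iterable[tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def _gtf_line(
    seqid: str,
    feature: str,
    start: int,
    end: int,
    strand: str,
    attrs: Iterable[tuple[str, str]],
    score: str = ".",
    frame: str = ".",
) -> str:
    return "\t".join(
        [seqid, "txrefine", feature, str(start), str(end), score, strand, frame,
         _format_attrs(attrs)]
    )


def write_gtf(ann: Annotation, dest: IO[str] | None = None) -> str:
    """Serialize to GTF2.2 text; deterministic ordering and attribute layout.

    Genes are emitted in (seqid, start, id) order, each followed by its
    transcripts in (start, id) order, exons by start, then any pass-through
    features.  ``gene_id`` and ``transcript_id`` always lead the attribute
    column; remaining attributes follow in sorted key order.
    """
    buf = io.StringIO()
    for gid in ann.sorted_gene_ids():
        gene = ann.genes[gid]
        gene_pairs = [("gene_id", gid)] + sorted(gene.attributes.items())
        buf.write(
            _gtf_line(gene.span.seqid, "gene", gene.span.start, gene.span.end,
                      gene.span.strand, gene_pairs) + "\n"
        )
        txs = sorted(gene.transcript_ids,
                     key=lambda tid: (ann.transcripts[tid].start, tid))
        for tid in txs:
            t = ann.transcripts[tid]
            pairs = [("gene_id", gid), ("transcript_id", tid)]
            if t.coverage is not None:
                pairs.append(("cov", f"{t.coverage:.6f}"))
            pairs.extend(sorted(t.attributes.items()))
            buf.write(
                _gtf_line(t.seqid, "transcript", t.start, t.end, t.strand, pairs) + "\n"
            )
            for e in t.exons:
                epairs = [("gene_id", gid), ("transcript_id", tid),
                          ("exon_number", str(e.rank))]
                buf.write(
                    _gtf_line(e.interval.seqid, "exon", e.interval.start,
                              e.interval.end, e.interval.strand, epairs) + "\n"
                )
            for f in t.extra_features:
                fpairs = [("gene_id", gid), ("transcript_id", tid)] + list(f.attributes)
                buf.write(
                    _gtf_line(f.interval.seqid, f.feature_type, f.interval.start,
                              f.interval.end, f.interval.strand, fpairs,
                              score=f.score, frame=f.frame) + "\n"
                )
    text = buf.getvalue()
    if dest is not None:
        dest.write(text)
    return text
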