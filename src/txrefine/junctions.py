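"""Splice-junction support filter for candidate transcripts.

Assembled transcripts are only as trustworthy as their novel splice
junctions.  A junction already present in the reference annotation needs no
fresh evidence; every *novel* junction must be backed by a minimum number of
spliced reads, each anchored by a minimum aligned block on both sides.
Candidates carrying a per-transcript read coverage estimate must additionally
clear a coverage floor.  Defaults (4 reads, 15 bp anchors, coverage 10)
reproduce a stringent assembly-stage configuration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

from .errors import ContractError
from .model import Annotation, intron_chain

JunctionKey = tuple[str, int, int, str]  # (seqid, donor_end, acceptor_start, strand)


@dataclass(frozen=True)
class JunctionEvidence:
    seqid: str
    donor_end: int
    acceptor_start: int
    strand: str
    read_count: int
    min_anchor: int

    def __post_init__(self) -> None:
        if self.acceptor_start <= self.donor_end:
            raise ContractError(
                f"junction {self.seqid}:{self.donor_end}-{self.acceptor_start}: "
                "acceptor_start must exceed donor_end"
            )
        if self.read_count < 0 or self.min_anchor < 0:
            raise ContractError("read_count and min_anchor must be nonnegative")


@dataclass(frozen=True)
class JunctionFilterConfig:
    min_junction_reads: int = 4
    min_anchor: int = 15
    min_coverage: float = 10.0

    def __post_init__(self) -> None:
        if min(self.min_junction_reads, self.min_anchor, self.min_coverage) < 0:
            raise ContractError("junction filter thresholds must be nonnegative")


def reference_junction_set(ref: Annotation) -> set[JunctionKey]:
    """All stranded splice junctions present in the reference annotation."""
    out: set[JunctionKey] = set()
    for t in ref.transcripts.values():
        for donor, acceptor in intron_chain(t):
            out.add((t.seqid, donor, acceptor, t.strand))
    return out


def _in_reference(key: JunctionKey, ref_junctions: set[JunctionKey]) -> bool:
    seqid, d, a, strand = key
    if key in ref_junctions:
        return True
    # unstranded matches either orientation, and vice versa
    if strand == ".":
        return (seqid, d, a, "+") in ref_junctions or (seqid, d, a, "-") in ref_junctions
    return (seqid, d, a, ".") in ref_junctions


def _evidence_for(
    key: JunctionKey, evidence: dict[JunctionKey, JunctionEvidence]
) -> JunctionEvidence | None:
    seqid, d, a, strand = key
    hit = evidence.get(key)
    if hit is not None:
        return hit
    if strand == ".":
        for s in ("+", "-"):
            hit = evidence.get((seqid, d, a, s))
            if hit is not None:
                return hit
        return None
    return evidence.get((seqid, d, a, "."))


def filter_by_junction_support(
    candidates: Annotation,
    ref_junctions: set[JunctionKey],
    evidence: Iterable[JunctionEvidence],
    cfg: JunctionFilterConfig = JunctionFilterConfig(),
) -> tuple[set[str], dict[str, str]]:
    """Partition candidate transcript ids into (pass set, fail reasons).

    A candidate passes iff every novel junction of its intron chain has
    evidence with ``read_count >= min_junction_reads`` and ``min_anchor >=
    cfg.min_anchor``, and (when a coverage attribute is present) coverage is
    at least ``min_coverage``.  A novel junction with no evidence row counts
    as zero reads.  The fail reason names the first violated junction, or the
    coverage rule.
    """
    table: dict[JunctionKey, JunctionEvidence] = {}
    for ev in evidence:
        table[(ev.seqid, ev.donor_end, ev.acceptor_start, ev.strand)] = ev

    passed: set[str] = set()
    failed: dict[str, str] = {}
    for tid, t in candidates.transcripts.items():
        reason = None
        for donor, acceptor in intron_chain(t):
            key = (t.seqid, donor, acceptor, t.strand)
            if _in_reference(key, ref_junctions):
                continue
            hit = _evidence_for(key, table)
            reads = hit.read_count if hit is not None else 0
            anchor = hit.min_anchor if hit is not None else 0
            loc = f"{t.seqid}:{donor}-{acceptor}"
            if reads < cfg.min_junction_reads:
                reason = (
                    f"junction {loc}: {reads} supporting reads "
                    f"< {cfg.min_junction_reads}"
                )
                break
            if anchor < cfg.min_anchor:
                reason = f"junction {loc}: min anchor {anchor} < {cfg.min_anchor}"
                break
        if reason is None and t.coverage is not None and t.coverage < cfg.min_coverage:
            reason = f"coverage {t.coverage:g} < {cfg.min_coverage:g}"
        if reason is None:
            passed.add(tid)
        else:
            failed[tid] = reason
    return passed, failed


# ---------------------------------------------------------------------------
# evidence table I/O
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = ("seqid", "donor_end", "acceptor_start", "strand",
                     "read_count", "min_anchor")


def read_junction_table(source: str | Path | IO[str]) -> list[JunctionEvidence]:
    """Read a tab-delimited evidence table with the canonical header."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return read_junction_table(fh)
    reader = csv.DictReader(source, delimiter="\t")
    missing = set(_EVIDENCE_COLUMNS) - set(reader.fieldnames or ())
    if missing:
        raise ContractError(f"junction table missing columns: {sorted(missing)}")
    return [
        JunctionEvidence(
            seqid=row["seqid"],
            donor_end=int(row["donor_end"]),
            acceptor_start=int(row["acceptor_start"]),
            strand=row["strand"],
            read_count=int(row["read_count"]),
            min_anchor=int(row["min_anchor"]),
        )
        for row in reader
    ]


def write_junction_table(evidence: Iterable[JunctionEvidence], dest: IO[str]) -> None:
    dest.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
    for ev in sorted(evidence, key=lambda e: (e.seqid, e.donor_end, e.acceptor_start,
                                              e.strand)):
        dest.write(
            f"{ev.seqid}\t{ev.donor_end}\t{ev.acceptor_start}\t{ev.strand}"
            f"\t{ev.read_count}\t{ev.min_anchor}\n"
        )
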