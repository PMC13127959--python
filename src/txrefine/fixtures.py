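"""Seeded generator of toy refinement inputs with known ground truth.

The generator lays out multi-isoform gene loci along a handful of
soft-masked scaffolds, then plants one candidate transcript per scenario:

* ``exact_match``     — a byte-for-byte structural copy of a reference isoform;
* ``novel_isoform``   — an exon-skipping variant of a host gene (its skip
  junction exists nowhere in the reference);
* ``join_evidence``   — a spanning transcript touching one exon of each of
  *k* consecutive same-strand genes (k follows a configurable cardinality
  distribution, by default the 2..7 mix observed in real refinement runs);
* ``novel_gene``      — a transcript on intergenic sequence;
* ``antisense``       — a reference-isoform copy on the opposite strand,
  which a strand-aware classifier must call ``novel_gene``.

Expression rows are built so that each filterable candidate violates exactly
its planted rule (or none) at the default thresholds, using small integer
counts so the strict-inequality boundaries stay exact.  Junction evidence
supports every planted novel junction at a configurable level.  Everything
is a pure function of the seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ConfigError
from .exprfilter import ExpressionMatrix
from .junctions import (JunctionEvidence, reference_junction_set,
                        write_junction_table, read_junction_table)
from .model import (Annotation, Exon, GenomicInterval, Transcript, intron_chain,
                    read_gtf, write_gtf)

CATEGORIES = ("exact_match", "novel_isoform", "join_evidence", "novel_gene",
              "antisense")
VIOLATIONS = ("none", "sample_fraction", "total_reads", "gene_fraction")

# cardinality mix of joined neighbours, weighted like a typical refinement run
DEFAULT_JOIN_WEIGHTS = {2: 677, 3: 140, 4: 34, 5: 24, 6: 8, 7: 2}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_scaffolds: int = 3
    n_candidates: int = 40
    n_background_genes: int = 6
    isoforms_per_gene: tuple[int, int] = (1, 3)
    exons_per_transcript: tuple[int, int] = (2, 5)
    category_mix: dict[str, float] = field(
        default_factory=lambda: {
            "exact_match": 0.20,
            "novel_isoform": 0.25,
            "join_evidence": 0.15,
            "novel_gene": 0.30,
            "antisense": 0.10,
        }
    )
    join_weights: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_JOIN_WEIGHTS)
    )
    mask_fraction: float = 0.20
    n_samples: int = 21
    filter_violation_mix: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.55,
            "sample_fraction": 0.15,
            "total_reads": 0.15,
            "gene_fraction": 0.15,
        }
    )
    junction_read_support: int = 10
    junction_anchor: int = 25
    candidate_coverage: float = 25.0

    def validate(self) -> None:
        for name, mix, keys in (
            ("category_mix", self.category_mix, CATEGORIES),
            ("filter_violation_mix", self.filter_violation_mix, VIOLATIONS),
        ):
            if set(mix) - set(keys):
                raise ConfigError(f"{name} has unknown keys: {set(mix) - set(keys)}")
            if any(v < 0 for v in mix.values()):
                raise ConfigError(f"{name} has negative proportions")
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ConfigError(f"{name} proportions must sum to 1")
        if self.n_candidates < 0 or self.n_samples < 1 or self.n_scaffolds < 1:
            raise ConfigError("n_candidates/n_samples/n_scaffolds out of range")
        lo, hi = self.exons_per_transcript
        if not 1 <= lo <= hi:
            raise ConfigError("exons_per_transcript range is empty")
        lo, hi = self.isoforms_per_gene
        if not 1 <= lo <= hi:
            raise ConfigError("isoforms_per_gene range is empty")
        if not self.join_weights or min(self.join_weights) < 2:
            raise ConfigError("join cardinalities must all be >= 2")
        if not 0 <= self.mask_fraction <= 1:
            raise ConfigError("mask_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    transcript_id: str
    category: str  # the classifier's expected code
    antisense: bool = False
    join_members: tuple[str, ...] = ()
    host_gene: str | None = None  # exact/isoform/antisense host
    matched_transcript: str | None = None  # exact_match only
    expr_violation: str | None = None  # None for exact_match (not filterable)
    expr_group: str | None = None  # gene grouping key used for rule 3


@dataclass
class FixtureBundle:
    genome: dict[str, str]
    reference: Annotation
    candidates: Annotation
    truth: dict[str, TruthRecord]
    expression: ExpressionMatrix
    junctions: list[JunctionEvidence]
    gene_of: dict[str, str]  # every matrix transcript -> expression gene group
    join_groups: list[tuple[str, ...]]  # planted merge components (gene ids)

    @property
    def truth_labels(self) -> dict[str, str]:
        return {tid: rec.category for tid, rec in self.truth.items()}


# ---------------------------------------------------------------------------
# apportionment helpers
# ---------------------------------------------------------------------------


def _apportion(n: int, mix: dict[str, float], order: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder apportionment of n items over proportions (deterministic)."""
    raw = {k: n * mix.get(k, 0.0) for k in order}
    counts = {k: int(raw[k]) for k in order}
    rest = n - sum(counts.values())
    by_frac = sorted(order, key=lambda k: (-(raw[k] - counts[k]), order.index(k)))
    for k in by_frac[:rest]:
        counts[k] += 1
    return counts


def _spread(total: float, n_expressed: int, n_samples: int,
            rng: random.Random) -> list[float]:
    """Distribute `total` reads over n_expressed of n_samples samples (>0 each)."""
    cols = sorted(rng.sample(range(n_samples), n_expressed))
    values = [0.0] * n_samples
    if total >= n_expressed and float(total).is_integer():
        base, rest = int(total) // n_expressed, int(total) % n_expressed
        for i, c in enumerate(cols):
            values[c] = base + (1 if i < rest else 0)
    else:
        for c in cols:
            values[c] = total / n_expressed
    return values


def _min_samples_at_or_above(n: int, frac: float = 0.3) -> int:
    """Smallest m with m/n >= frac (exact rational arithmetic for frac=3/10)."""
    m = -((-3 * n) // 10)
    return max(1, m)


def _max_samples_below(n: int, frac: float = 0.3) -> int:
    """Largest m >= 1 with m/n < frac."""
    return max(1, (3 * n - 1) // 10)


# ---------------------------------------------------------------------------
# locus construction
# ---------------------------------------------------------------------------


class _Layout:
    """Sequential placement of gene loci along scaffolds."""

    def __init__(self, cfg: FixtureConfig, rng: random.Random) -> None:
        self.cfg = cfg
        self.rng = rng
        self.cursor = {f"scaf{i + 1:02d}": 1000 for i in range(cfg.n_scaffolds)}
        self._next = 0

    def pick_scaffold(self) -> str:
        names = sorted(self.cursor)
        name = names[self._next % len(names)]
        self._next += 1
        return name

    def place_slots(self, seqid: str, n_slots: int) -> list[tuple[int, int]]:
        pos = self.cursor[seqid]
        slots = []
        for _ in range(n_slots):
            length = self.rng.randint(120, 300)
            slots.append((pos, pos + length - 1))
            pos += length + self.rng.randint(80, 200)
        self.cursor[seqid] = pos + self.rng.randint(600, 1400)
        return slots


def _exons(slots: list[tuple[int, int]], seqid: str, strand: str) -> list[Exon]:
    return [
        Exon(GenomicInterval(seqid, s, e, strand), rank=i + 1)
        for i, (s, e) in enumerate(slots)
    ]


@dataclass
class _Locus:
    gene_id: str
    seqid: str
    strand: str
    slots: list[tuple[int, int]]
    isoform_runs: list[tuple[int, int]]  # contiguous slot runs used by ref isoforms


def _build_reference_gene(
    ref: Annotation, layout: _Layout, rng: random.Random, gene_id: str,
    min_slots: int, seqid: str | None = None, strand: str | None = None,
) -> _Locus:
    cfg = layout.cfg
    seqid = seqid or layout.pick_scaffold()
    lo, hi = cfg.exons_per_transcript
    n_slots = rng.randint(max(min_slots, lo), max(min_slots, hi))
    slots = layout.place_slots(seqid, n_slots)
    strand = strand or rng.choice("+-")
    n_iso = rng.randint(*cfg.isoforms_per_gene)
    runs = [(0, n_slots - 1)]
    for _ in range(n_iso - 1):
        i0 = rng.randint(0, n_slots - 1)
        i1 = rng.randint(i0, n_slots - 1)
        if (i0, i1) not in runs:
            runs.append((i0, i1))
    for n, (i0, i1) in enumerate(runs, start=1):
        ref.add_transcript(
            Transcript(
                id=f"{gene_id}.t{n}",
                gene_id=gene_id,
                exons=_exons(slots[i0:i1 + 1], seqid, strand),
                source="reference",
            )
        )
    return _Locus(gene_id, seqid, strand, slots, runs)


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------


def generate(cfg: FixtureConfig) -> FixtureBundle:
    cfg.validate()
    rng = random.Random(cfg.seed)

    counts = _apportion(cfg.n_candidates, cfg.category_mix, CATEGORIES)
    ref = Annotation()
    cands = Annotation()
    layout = _Layout(cfg, rng)
    truth: dict[str, TruthRecord] = {}
    join_groups: list[tuple[str, ...]] = []
    gene_serial = 0
    cand_serial = 0

    def next_gene_id() -> str:
        nonlocal gene_serial
        gene_serial += 1
        return f"GBI_{gene_serial:05d}"

    def next_cand_id() -> str:
        nonlocal cand_serial
        cand_serial += 1
        return f"STRG.{cand_serial}.1"

    def add_candidate(exons: list[Exon], **truth_kw) -> str:
        tid = next_cand_id()
        cands.add_transcript(
            Transcript(id=tid, gene_id=f"CANDG.{tid}", exons=exons,
                       source="candidate", coverage=cfg.candidate_coverage)
        )
        truth[tid] = TruthRecord(transcript_id=tid, **truth_kw)
        return tid

    # scenario order is shuffled once so categories interleave along scaffolds
    scenario: list[tuple] = (
        [("exact_match",)] * counts["exact_match"]
        + [("novel_isoform",)] * counts["novel_isoform"]
        + [("novel_gene",)] * counts["novel_gene"]
        + [("antisense",)] * counts["antisense"]
    )
    card_keys = sorted(cfg.join_weights)
    weights = [cfg.join_weights[k] for k in card_keys]
    for _ in range(counts["join_evidence"]):
        scenario.append(("join_evidence", rng.choices(card_keys, weights)[0]))
    rng.shuffle(scenario)

    for item in scenario:
        kind = item[0]
        if kind == "exact_match":
            locus = _build_reference_gene(ref, layout, rng, next_gene_id(), 1)
            i0, i1 = locus.isoform_runs[0]
            tid = add_candidate(
                _exons(locus.slots[i0:i1 + 1], locus.seqid, locus.strand),
                category="exact_match", host_gene=locus.gene_id,
                matched_transcript=f"{locus.gene_id}.t1",
                expr_group=locus.gene_id,
            )
        elif kind == "novel_isoform":
            locus = _build_reference_gene(ref, layout, rng, next_gene_id(), 3)
            skip = rng.randint(1, len(locus.slots) - 2)
            kept = locus.slots[:skip] + locus.slots[skip + 1:]
            add_candidate(
                _exons(kept, locus.seqid, locus.strand),
                category="novel_isoform", host_gene=locus.gene_id,
                expr_group=locus.gene_id,
            )
        elif kind == "antisense":
            locus = _build_reference_gene(ref, layout, rng, next_gene_id(), 1)
            i0, i1 = locus.isoform_runs[0]
            flipped = "-" if locus.strand == "+" else "+"
            add_candidate(
                _exons(locus.slots[i0:i1 + 1], locus.seqid, flipped),
                category="novel_gene", antisense=True, host_gene=locus.gene_id,
            )
        elif kind == "novel_gene":
            seqid = layout.pick_scaffold()
            n_slots = rng.randint(1, 3)
            slots = layout.place_slots(seqid, n_slots)
            add_candidate(
                _exons(slots, seqid, rng.choice("+-")),
                category="novel_gene",
            )
        else:  # join_evidence of cardinality k
            k = item[1]
            seqid = layout.pick_scaffold()
            strand = rng.choice("+-")
            # members share one scaffold and strand so a spanning transcript
            # can link them
            members = [
                _build_reference_gene(ref, layout, rng, next_gene_id(), 1,
                                      seqid=seqid, strand=strand)
                for _ in range(k)
            ]
            member_ids = tuple(m.gene_id for m in members)
            join_groups.append(member_ids)
            span_exons = [
                Exon(GenomicInterval(seqid, m.slots[0][0], m.slots[0][1], strand),
                     rank=i + 1)
                for i, m in enumerate(members)
            ]
            add_candidate(
                span_exons,
                category="join_evidence", join_members=member_ids,
                expr_group="+".join(member_ids),
            )

    for i in range(cfg.n_background_genes):
        _build_reference_gene(ref, layout, rng, next_gene_id(), 1)

    # ------------------------------------------------------------------
    # junction evidence for every planted novel junction, plus decoys
    # ------------------------------------------------------------------
    ref_junctions = reference_junction_set(ref)
    evidence: dict[tuple, JunctionEvidence] = {}
    for t in cands.transcripts.values():
        for donor, acceptor in intron_chain(t):
            key = (t.seqid, donor, acceptor, t.strand)
            if key in ref_junctions:
                continue
            evidence[key] = JunctionEvidence(
                seqid=t.seqid, donor_end=donor, acceptor_start=acceptor,
                strand=t.strand, read_count=cfg.junction_read_support,
                min_anchor=cfg.junction_anchor,
            )
    for i in range(5):  # unsupported decoy junctions far from any locus
        seqid = sorted(layout.cursor)[i % cfg.n_scaffolds]
        pos = layout.cursor[seqid] + 5000 + 400 * i
        key = (seqid, pos, pos + 150, "+")
        evidence[key] = JunctionEvidence(seqid, pos, pos + 150, "+",
                                         read_count=1, min_anchor=5)
    junctions = [evidence[k] for k in sorted(evidence)]

    # ------------------------------------------------------------------
    # expression matrix with planted single-rule violations
    # ------------------------------------------------------------------
    expression, gene_of, truth = _build_expression(cfg, rng, ref, cands, truth,
                                                   join_groups)

    genome = _build_genome(cfg, rng, layout)
    return FixtureBundle(
        genome=genome, reference=ref, candidates=cands, truth=truth,
        expression=expression, junctions=junctions, gene_of=gene_of,
        join_groups=join_groups,
    )


def _build_expression(
    cfg: FixtureConfig,
    rng: random.Random,
    ref: Annotation,
    cands: Annotation,
    truth: dict[str, TruthRecord],
    join_groups: list[tuple[str, ...]],
) -> tuple[ExpressionMatrix, dict[str, str], dict[str, TruthRecord]]:
    n = cfg.n_samples
    merged_group = {g: "+".join(group) for group in join_groups for g in group}

    gene_of: dict[str, str] = {}
    for tid, t in ref.transcripts.items():
        gene_of[tid] = merged_group.get(t.gene_id, t.gene_id)
    for tid, rec in truth.items():
        gene_of[tid] = rec.expr_group or tid

    # assign a violation plan to every filterable candidate
    filterable = [tid for tid, rec in truth.items()
                  if rec.category != "exact_match"]
    quotas = _apportion(len(filterable), cfg.filter_violation_mix, VIOLATIONS)
    if quotas["sample_fraction"] > 0 and (3 * n - 1) // 10 < 1:
        raise ConfigError(
            f"cannot plant sample_fraction violations with {n} samples"
        )
    eligible_gf = [t for t in filterable
                   if any(gene_of[o] == gene_of[t] for o in ref.transcripts)]
    if quotas["gene_fraction"] > len(eligible_gf):
        raise ConfigError(
            "not enough candidates with gene siblings to plant "
            f"{quotas['gene_fraction']} gene_fraction violations"
        )
    plan: dict[str, str] = {}
    pool = sorted(filterable)
    rng.shuffle(pool)
    gf_pool = [t for t in pool if t in set(eligible_gf)]
    for t in gf_pool[: quotas["gene_fraction"]]:
        plan[t] = "gene_fraction"
    rest = [t for t in pool if t not in plan]
    cursor = 0
    for rule in ("sample_fraction", "total_reads", "none"):
        for _ in range(quotas[rule] if rule != "none" else len(rest) - cursor):
            if cursor >= len(rest):
                break
            plan[rest[cursor]] = rule
            cursor += 1

    # sibling reference budgets depend on the group's planted rule
    group_plan: dict[str, str] = {}
    for tid, rule in plan.items():
        group_plan[gene_of[tid]] = rule

    # a gene_fraction candidate gets max(12, m_on) reads; its siblings must
    # jointly exceed 9x that so the fraction falls strictly below 0.1
    m_on = _min_samples_at_or_above(n)
    gf_candidate_total = max(12, m_on)

    rows: dict[str, list[float]] = {}
    for tid in sorted(ref.transcripts):
        rule = group_plan.get(gene_of[tid])
        if rule == "total_reads":
            target = rng.randint(1, 2)  # keep the gene denominator tiny
        elif rule == "gene_fraction":
            target = None  # budgeted jointly below
        else:
            target = rng.randint(20, 40)
        if target is not None:
            rows[tid] = _spread(target, min(n, target), n, rng)

    for group, rule in group_plan.items():
        if rule != "gene_fraction":
            continue
        sibs = sorted(t for t in ref.transcripts if gene_of[t] == group)
        budget = 9 * gf_candidate_total + 12 + rng.randint(0, 40)
        per = -(-budget // len(sibs))
        for s in sibs:
            rows[s] = _spread(per, min(n, per), n, rng)

    sib_total: dict[str, float] = {}
    for tid in ref.transcripts:
        g = gene_of[tid]
        sib_total[g] = sib_total.get(g, 0.0) + sum(rows[tid])

    for tid in sorted(cands.transcripts):
        rec = truth[tid]
        sib = sib_total.get(gene_of[tid], 0.0)
        rule = plan.get(tid)
        if rec.category == "exact_match":
            rows[tid] = _spread(rng.randint(20, 40), m_on, n, rng)
            continue
        if rule == "sample_fraction":
            # too few expressed samples; total and gene fraction stay healthy
            m = _max_samples_below(n)
            total = max(m, 10, -(-int(sib) // 9) + 1)
            rows[tid] = _spread(float(total), m, n, rng)
        elif rule == "total_reads":
            # 9 < 10 total reads; enough samples; tiny siblings keep rule 3 safe
            rows[tid] = _spread(9.0, m_on, n, rng)
        elif rule == "gene_fraction":
            rows[tid] = _spread(float(gf_candidate_total), m_on, n, rng)
        else:  # "none": pass every rule with headroom
            m = max(m_on, -(-n // 2))
            total = max(m, 10, -(-int(sib) // 9) + 1)
            rows[tid] = _spread(float(total), m, n, rng)
        truth[tid] = TruthRecord(
            transcript_id=tid, category=rec.category, antisense=rec.antisense,
            join_members=rec.join_members, host_gene=rec.host_gene,
            matched_transcript=rec.matched_transcript, expr_violation=rule,
            expr_group=rec.expr_group,
        )

    sample_ids = [f"S{i + 1:02d}" for i in range(n)]
    index = sorted(rows)
    df = pd.DataFrame([rows[t] for t in index], index=index, columns=sample_ids)
    return ExpressionMatrix(df), gene_of, truth


def _build_genome(cfg: FixtureConfig, rng: random.Random, layout: _Layout
                  ) -> dict[str, str]:
    genome = {}
    masked_per_kb = int(1000 * cfg.mask_fraction)
    for seqid in sorted(layout.cursor):
        length = layout.cursor[seqid] + 10_000
        bases = rng.choices("ACGT", k=length)
        for block in range(0, length, 1000):
            for i in range(block, min(block + masked_per_kb, length)):
                bases[i] = bases[i].lower()
        genome[seqid] = "".join(bases)
    return genome


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TRUTH_COLUMNS = ("transcript_id", "category", "antisense", "join_members",
                  "host_gene", "matched_transcript", "expr_violation", "expr_group")


def write_bundle(bundle: FixtureBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for seqid in sorted(bundle.genome):
            fh.write(f">{seqid}\n")
            seq = bundle.genome[seqid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    (outdir / "reference.gtf").write_text(write_gtf(bundle.reference))
    (outdir / "candidates.gtf").write_text(write_gtf(bundle.candidates))
    bundle.expression.write_tsv(outdir / "expression.tsv")
    with open(outdir / "junctions.tsv", "w") as fh:
        write_junction_table(bundle.junctions, fh)
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for tid in sorted(bundle.truth):
            r = bundle.truth[tid]
            fh.write(
                f"{tid}\t{r.category}\t{int(r.antisense)}\t"
                f"{','.join(r.join_members)}\t{r.host_gene or ''}\t"
                f"{r.matched_transcript or ''}\t{r.expr_violation or ''}\t"
                f"{r.expr_group or ''}\n"
            )
    with open(outdir / "gene_of.tsv", "w") as fh:
        fh.write("transcript_id\tgene\n")
        for tid in sorted(bundle.gene_of):
            fh.write(f"{tid}\t{bundle.gene_of[tid]}\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if name is not None:
                genome[name] = "".join(chunks)
            name = line[1:].split()[0]
            chunks = []
        else:
            chunks.append(line.strip())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


def read_bundle(indir: str | Path) -> FixtureBundle:
    indir = Path(indir)
    truth: dict[str, TruthRecord] = {}
    join_groups: list[tuple[str, ...]] = []
    lines = (indir / "truth.tsv").read_text().splitlines()
    for line in lines[1:]:
        cols = line.split("\t")
        rec = TruthRecord(
            transcript_id=cols[0], category=cols[1], antisense=bool(int(cols[2])),
            join_members=tuple(cols[3].split(",")) if cols[3] else (),
            host_gene=cols[4] or None, matched_transcript=cols[5] or None,
            expr_violation=cols[6] or None, expr_group=cols[7] or None,
        )
        truth[rec.transcript_id] = rec
        if rec.join_members and rec.join_members not in join_groups:
            join_groups.append(rec.join_members)
    gene_of = {}
    for line in (indir / "gene_of.tsv").read_text().splitlines()[1:]:
        tid, gene = line.split("\t")
        gene_of[tid] = gene
    return FixtureBundle(
        genome=read_genome_fasta(indir / "genome.fa"),
        reference=read_gtf(indir / "reference.gtf", "reference"),
        candidates=read_gtf(indir / "candidates.gtf", "candidate"),
        truth=truth,
        expression=ExpressionMatrix.read_tsv(indir / "expression.tsv"),
        junctions=read_junction_table(indir / "junctions.tsv"),
        gene_of=gene_of,
        join_groups=join_groups,
    )
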