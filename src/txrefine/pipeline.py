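"""End-to-end refinement driver: junction filter -> classify -> merge ->
expression filter -> integrate -> summarize.

The single-command driver keeps the intermediate transcriptome (reference
plus all junction-passing novel transcripts) in memory; ``emit_intermediate``
writes it out for inspection.  Every stage logs in/kept/removed counts, and
the artifact set written to ``outdir`` is deterministic for identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classify import ComparisonCode, classify_all, write_classification_table
from .errors import ConfigError
from .exprfilter import (ExpressionFilterConfig, ExpressionMatrix, FilterReport,
                         filter_novel_transcripts)
from .fixtures import read_genome_fasta
from .integrate import (IdentifierScheme, IntegrationResult,
                        cluster_novel_transcripts, integrate, softmask_fraction)
from .junctions import (JunctionFilterConfig, filter_by_junction_support,
                        read_junction_table, reference_junction_set)
from .merge import build_merge_components, merge_distribution, write_merge_table
from .model import read_gtf, write_gtf
from .summary import (assembly_summary, busco_gene_reconcile,
                      merge_distribution_text, read_busco_hits)

log = logging.getLogger("txrefine")


@dataclass
class RunConfig:
    reference: Path
    candidates: Path
    outdir: Path
    expression: Path | None = None
    junctions: Path | None = None
    genome: Path | None = None
    busco: Path | None = None
    busco_total: int = 1013
    junction_filter: JunctionFilterConfig = field(default_factory=JunctionFilterConfig)
    expression_filter: ExpressionFilterConfig = field(
        default_factory=ExpressionFilterConfig
    )
    gene_prefix: str = "GBIG_G_"
    pad_width: int = 6
    emit_intermediate: bool = False

    def __post_init__(self) -> None:
        for name in ("reference", "candidates", "expression", "junctions",
                     "genome", "busco"):
            value = getattr(self, name)
            if value is None:
                continue
            path = Path(value)
            setattr(self, name, path)
            if not path.exists():
                raise ConfigError(f"{name} input does not exist: {path}")
        self.outdir = Path(self.outdir)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML key-value file; kwargs override file keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    jf_keys = {f.name for f in fields(JunctionFilterConfig)}
    ef_keys = {f.name for f in fields(ExpressionFilterConfig)}
    jf = JunctionFilterConfig(**{k: raw.pop(k) for k in list(raw) if k in jf_keys})
    ef = ExpressionFilterConfig(**{k: raw.pop(k) for k in list(raw) if k in ef_keys})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(junction_filter=jf, expression_filter=ef, **raw)


@dataclass
class PipelineResult:
    integration: IntegrationResult
    counts: dict[str, int]
    filter_report: FilterReport | None


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    ref = read_gtf(cfg.reference, "reference")
    cands = read_gtf(cfg.candidates, "candidate")
    counts["reference_genes"] = len(ref.genes)
    counts["reference_transcripts"] = len(ref.transcripts)
    counts["candidates_in"] = len(cands.transcripts)
    log.info("loaded %d reference genes / %d transcripts; %d candidates",
             len(ref.genes), len(ref.transcripts), len(cands.transcripts))

    # -- stage 1: junction support -------------------------------------
    evidence = read_junction_table(cfg.junctions) if cfg.junctions else []
    ref_junctions = reference_junction_set(ref)
    jpass, jfail = filter_by_junction_support(
        cands, ref_junctions, evidence, cfg.junction_filter
    )
    counts["junction_pass"] = len(jpass)
    counts["junction_fail"] = len(jfail)
    log.info("junction filter: %d pass, %d fail", len(jpass), len(jfail))

    # -- stage 2: classification ---------------------------------------
    surviving = _subset(cands, jpass)
    classified = classify_all(surviving, ref)
    for code in ComparisonCode:
        counts[f"classified_{code.value}"] = sum(
            1 for c in classified if c.code is code
        )
    log.info("classification: %s",
             {code.value: counts[f"classified_{code.value}"]
              for code in ComparisonCode})
    with open(cfg.outdir / "classified.tsv", "w") as fh:
        write_classification_table(classified, fh)

    # -- stage 3: expression filter ------------------------------------
    by_id = {c.transcript_id: c for c in classified}
    report: FilterReport | None = None
    if cfg.expression:
        matrix = ExpressionMatrix.read_tsv(cfg.expression)
        gene_of = _expression_gene_map(ref, cands, classified, matrix)
        novel_ids = {
            c.transcript_id for c in classified
            if c.code is not ComparisonCode.EXACT_MATCH
        }
        report = filter_novel_transcripts(
            matrix, novel_ids, gene_of, cfg.expression_filter
        )
        kept = report.kept_ids
        counts["expression_kept"] = len(kept)
        counts["expression_removed"] = len(report.removed_ids)
        log.info("expression filter: %d kept, %d removed",
                 len(kept), len(report.removed_ids))
        with open(cfg.outdir / "filter_report.tsv", "w") as fh:
            report.write_tsv(fh)
        survivors = [
            c for c in classified
            if c.code is ComparisonCode.EXACT_MATCH or c.transcript_id in kept
        ]
    else:
        survivors = list(classified)

    # -- stage 4: merge components from surviving evidence -------------
    components = build_merge_components(
        (c for c in survivors if c.code is ComparisonCode.JOIN_EVIDENCE), ref
    )
    counts["merge_components"] = len(components)
    dist = merge_distribution(components)
    log.info("merge: %d components, cardinalities %s", len(components), dist.counts)

    if cfg.emit_intermediate:
        inter = integrate(
            ref, classified, cands,
            build_merge_components(
                (c for c in classified if c.code is ComparisonCode.JOIN_EVIDENCE),
                ref,
            ),
            IdentifierScheme(cfg.gene_prefix, cfg.pad_width),
        )
        (cfg.outdir / "intermediate.gtf").write_text(write_gtf(inter.updated))

    # -- stage 5: integration ------------------------------------------
    result = integrate(
        ref, survivors, cands, components,
        IdentifierScheme(cfg.gene_prefix, cfg.pad_width),
    )
    counts["final_genes"] = len(result.updated.genes)
    counts["final_transcripts"] = len(result.updated.transcripts)
    counts["novel_genes"] = sum(
        1 for g in result.updated.genes if g not in ref.genes
        and g not in result.id_map.values()
    )
    counts["isoforms_added"] = sum(
        1 for s in result.provenance.values() if s == "isoform_added"
    )
    log.info("integration: %d genes, %d transcripts",
             counts["final_genes"], counts["final_transcripts"])

    (cfg.outdir / "updated.gtf").write_text(write_gtf(result.updated))
    with open(cfg.outdir / "provenance.tsv", "w") as fh:
        result.write_provenance(fh)
    assigned_components = [
        type(c)(
            new_gene_id=result.id_map.get(min(c.member_gene_ids), ""),
            member_gene_ids=c.member_gene_ids,
            evidence_transcript_ids=c.evidence_transcript_ids,
        )
        for c in components
    ]
    with open(cfg.outdir / "merges.tsv", "w") as fh:
        write_merge_table(assigned_components, fh)

    # -- stage 6: summary ----------------------------------------------
    sections = [
        assembly_summary(ref).as_text("reference"),
        assembly_summary(result.updated).as_text("updated"),
        "[merge distribution]\n" + merge_distribution_text(dist.counts),
        "[stage counts]\n" + "\n".join(
            f"  {k}: {v}" for k, v in sorted(counts.items())
        ),
    ]
    if cfg.genome:
        genome = read_genome_fasta(cfg.genome)
        sections.append("[soft-mask QC]\n" + _softmask_section(result, ref, genome))
    if cfg.busco:
        hits = read_busco_hits(cfg.busco)
        tx_to_gene = {
            tid: t.gene_id for tid, t in result.updated.transcripts.items()
        }
        table = busco_gene_reconcile(hits, tx_to_gene, cfg.busco_total)
        sections.append("[BUSCO gene-level]\n" + table.as_text())
    (cfg.outdir / "summary.txt").write_text("\n\n".join(sections) + "\n")

    return PipelineResult(integration=result, counts=counts, filter_report=report)


def _subset(cands, keep_ids):
    from .model import Annotation

    out = Annotation()
    for tid in sorted(keep_ids):
        out.add_transcript(cands.transcripts[tid])
    return out


def _expression_gene_map(ref, cands, classified, matrix) -> dict[str, str]:
    """Post-classification gene membership for the rule-3 denominator.

    Merged units pool their member genes' transcripts; novel loci are their
    own denominators.  Matrix transcripts excluded before this stage
    (junction-failed or exact-match candidates) map to themselves so they do
    not distort gene totals.
    """
    components = build_merge_components(
        (c for c in classified if c.code is ComparisonCode.JOIN_EVIDENCE), ref
    )
    unit_of_gene: dict[str, str] = {}
    for comp in components:
        unit = "+".join(sorted(comp.member_gene_ids))
        for g in comp.member_gene_ids:
            unit_of_gene[g] = unit

    gene_of: dict[str, str] = {tid: tid for tid in matrix.transcript_ids}
    for tid, t in ref.transcripts.items():
        gene_of[tid] = unit_of_gene.get(t.gene_id, t.gene_id)

    novel = [cands.transcripts[c.transcript_id] for c in classified
             if c.code is ComparisonCode.NOVEL_GENE]
    for cluster in cluster_novel_transcripts(novel):
        unit = "novel:" + cluster[0].id
        for t in cluster:
            gene_of[t.id] = unit

    for c in classified:
        if c.code is ComparisonCode.NOVEL_ISOFORM:
            gene_of[c.transcript_id] = unit_of_gene.get(
                c.overlapping_gene_ids[0], c.overlapping_gene_ids[0]
            )
        elif c.code is ComparisonCode.JOIN_EVIDENCE:
            gene_of[c.transcript_id] = unit_of_gene[c.overlapping_gene_ids[0]]
    return gene_of


def _softmask_section(result, ref, genome) -> str:
    ref_fracs, novel_fracs = [], []
    for tid, status in result.provenance.items():
        t = result.updated.transcripts[tid]
        frac = softmask_fraction(t, genome)
        (ref_fracs if tid in ref.transcripts else novel_fracs).append(frac)

    def mean(xs):
        return sum(xs) / len(xs) if xs else 0.0

    return (
        f"  reference transcripts: n={len(ref_fracs)} "
        f"mean_masked_fraction={mean(ref_fracs):.4f}\n"
        f"  novel transcripts:     n={len(novel_fracs)} "
        f"mean_masked_fraction={mean(novel_fracs):.4f}"
    )
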