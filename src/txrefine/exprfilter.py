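"""Three-rule expression filter for novel transcripts.

After requantifying all samples against the intermediate transcriptome, a
novel transcript is eliminated if it fails any of:

1. *sample fraction* — assigned expression (expected count > 0) in fewer
   than 30% of the input samples;
2. *total reads* — fewer than 10 reads summed across all samples;
3. *gene fraction* — its summed reads are less than 10% of all reads
   assigned to its gene (gene membership taken after classification and
   locus merging, so a merged unit pools its members' transcripts).

All three boundaries are strict-less-than failure conditions: exactly 10
total reads, or exactly 30% of samples, passes.  Reference transcripts are
never filtered.  Expected counts are RSEM-style nonnegative reals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Callable, Iterable, Mapping

import pandas as pd

from .errors import ContractError, MappingError

RULES = ("sample_fraction", "total_reads", "gene_fraction")


@dataclass
class ExpressionMatrix:
    """Transcripts x samples expected-count matrix (thin pandas wrapper)."""

    data: pd.DataFrame  # index: transcript ids; columns: sample ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ContractError("expression matrix labels must be unique")
        if (self.data.to_numpy() < 0).any():
            raise ContractError("expression matrix contains negative values")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @classmethod
    def read_tsv(cls, source: str | Path | IO[str]) -> "ExpressionMatrix":
        df = pd.read_csv(source, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df.astype(float))

    def write_tsv(self, dest: str | Path | IO[str]) -> None:
        self.data.to_csv(dest, sep="\t", index_label="transcript_id")


@dataclass(frozen=True)
class ExpressionFilterConfig:
    min_sample_fraction: float = 0.30
    min_total_reads: float = 10.0
    min_gene_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 <= self.min_sample_fraction <= 1 and 0 <= self.min_gene_fraction <= 1):
            raise ContractError("fraction thresholds must lie in [0, 1]")
        if self.min_total_reads < 0:
            raise ContractError("min_total_reads must be nonnegative")


@dataclass
class TranscriptVerdict:
    transcript_id: str
    kept: bool
    failed_rules: tuple[str, ...]
    expressed_sample_count: int
    total_reads: float
    gene_fraction: float


@dataclass
class FilterReport:
    verdicts: dict[str, TranscriptVerdict] = field(default_factory=dict)

    @property
    def kept_ids(self) -> set[str]:
        return {t for t, v in self.verdicts.items() if v.kept}

    @property
    def removed_ids(self) -> set[str]:
        return {t for t, v in self.verdicts.items() if not v.kept}

    def write_tsv(self, dest: IO[str]) -> None:
        dest.write(
            "transcript_id\tkept\tfailed_rules\texpressed_sample_count"
            "\ttotal_reads\tgene_fraction\n"
        )
        for tid in sorted(self.verdicts):
            v = self.verdicts[tid]
            dest.write(
                f"{tid}\t{int(v.kept)}\t{','.join(v.failed_rules)}\t"
                f"{v.expressed_sample_count}\t{v.total_reads:g}\t{v.gene_fraction:g}\n"
            )


def filter_novel_transcripts(
    m: ExpressionMatrix,
    novel_ids: Iterable[str],
    gene_of: Mapping[str, str] | Callable[[str], str],
    cfg: ExpressionFilterConfig = ExpressionFilterConfig(),
) -> FilterReport:
    """Judge each novel transcript against the three support rules.

    ``gene_of`` must resolve every transcript in the matrix; the gene
    denominator of rule 3 sums expected counts of all the gene's matrix
    transcripts over all samples jointly.  A zero gene total yields gene
    fraction 1 by convention (0/0 := 1, the transcript is all of nothing).
    """
    lookup = gene_of.__getitem__ if isinstance(gene_of, Mapping) else gene_of
    novel = sorted(set(novel_ids))
    missing = [t for t in novel if t not in m.data.index]
    if missing:
        raise MappingError(f"novel transcripts absent from matrix: {missing}")

    n_samples = len(m.sample_ids)
    totals = m.data.sum(axis=1)
    expressed = (m.data > 0).sum(axis=1)
    gene_totals: dict[str, float] = {}
    for tid in m.transcript_ids:
        try:
            gid = lookup(tid)
        except KeyError as exc:
            raise MappingError(f"no gene mapping for transcript {tid!r}") from exc
        gene_totals[gid] = gene_totals.get(gid, 0.0) + float(totals[tid])

    report = FilterReport()
    for tid in novel:
        total = float(totals[tid])
        n_expr = int(expressed[tid])
        gtotal = gene_totals[lookup(tid)]
        gfrac = total / gtotal if gtotal > 0 else 1.0
        failed = []
        if n_samples == 0 or n_expr / n_samples < cfg.min_sample_fraction:
            failed.append("sample_fraction")
        if total < cfg.min_total_reads:
            failed.append("total_reads")
        if gfrac < cfg.min_gene_fraction:
            failed.append("gene_fraction")
        report.verdicts[tid] = TranscriptVerdict(
            transcript_id=tid,
            kept=not failed,
            failed_rules=tuple(failed),
            expressed_sample_count=n_expr,
            total_reads=total,
            gene_fraction=gfrac,
        )
    return report
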