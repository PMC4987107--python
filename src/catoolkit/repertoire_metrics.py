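"""Per-genome and cross-genome repertoire statistics.

For each genome we count annotated proteins and distinct domain
architectures, split by whether the architecture carries a calcium-binding
superfamily, and derive:

* diversity fraction — the share of distinct architectures that contain at
  least one calcium-binding domain,
* redundancy ratio — proteins-per-architecture among calcium-binding
  architectures relative to proteins-per-architecture over the whole
  proteome (1.0 means calcium-binding architectures are duplicated exactly
  as much as average),
* abundance–diversity correlation — the Pearson correlation across genomes
  between the number of calcium-binding proteins and the number of distinct
  calcium-binding architectures, and
* the genome × superfamily occurrence matrix: how many proteins in each
  genome contain each registry superfamily (per protein, not per domain
  copy — a protein with two EF-hand domains counts once).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .core_model import GAP, CaBindingRegistry, contains_ca_domain
from .proteome_io import GenomeTable

logger = logging.getLogger(__name__)


class UndefinedMetricError(ValueError):
    """Raised when a ratio or correlation is undefined for the given data."""


@dataclass(frozen=True)
class GenomeRepertoireSummary:
    genome_id: str
    n_proteins_total: int
    n_archs_total: int
    n_ca_proteins: int
    n_ca_archs: int
    superfamily_counts: dict[int, int]
    taxon_group: str = "unknown"
    total_gene_count: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.n_ca_proteins <= self.n_proteins_total):
            raise ValueError("n_ca_proteins out of range")
        if not (0 <= self.n_ca_archs <= self.n_archs_total):
            raise ValueError("n_ca_archs out of range")
        if self.n_ca_proteins > 0 and self.n_ca_archs > self.n_ca_proteins:
            raise ValueError("more calcium architectures than calcium proteins")


def summarize_genome(table: GenomeTable, registry: CaBindingRegistry) -> GenomeRepertoireSummary:
    """Count proteins/architectures and their calcium-binding subsets.

    Architecture distinctness is at exact token-sequence level, gaps
    included. ``superfamily_counts[s]`` is the number of proteins whose
    architecture contains registry superfamily ``s`` at least once.
    """
    archs = [rec.architecture for rec in table.records]
    ca_flags = [contains_ca_domain(a, registry) for a in archs]
    sf_counts: dict[int, int] = {s: 0 for s in sorted(registry.id_set)}
    for arch in archs:
        present = {t for t in arch.tokens if t != GAP and t in registry.id_set}
        for s in present:
            sf_counts[s] += 1
    return GenomeRepertoireSummary(
        genome_id=table.genome_id,
        n_proteins_total=len(archs),
        n_archs_total=len(set(archs)),
        n_ca_proteins=sum(ca_flags),
        n_ca_archs=len({a for a, f in zip(archs, ca_flags) if f}),
        superfamily_counts=sf_counts,
        taxon_group=table.taxon_group,
        total_gene_count=table.total_gene_count,
    )


def diversity_fraction(summary: GenomeRepertoireSummary) -> float:
    """Fraction of distinct architectures containing a calcium-binding domain."""
    if summary.n_archs_total == 0:
        raise UndefinedMetricError(
            f"genome {summary.genome_id!r}: diversity fraction undefined (no architectures)"
        )
    return summary.n_ca_archs / summary.n_archs_total


def redundancy_ratio(summary: GenomeRepertoireSummary) -> float:
    """Proteins-per-architecture of the calcium subset over the proteome-wide value."""
    if summary.n_ca_archs == 0 or summary.n_archs_total == 0:
        raise UndefinedMetricError(
            f"genome {summary.genome_id!r}: redundancy ratio undefined "
            f"(n_ca_archs={summary.n_ca_archs}, n_archs_total={summary.n_archs_total})"
        )
    return (summary.n_ca_proteins / summary.n_ca_archs) / (
        summary.n_proteins_total / summary.n_archs_total
    )


def abundance_diversity_correlation(summaries: Sequence[GenomeRepertoireSummary]) -> float:
    """Pearson r across genomes: calcium-binding proteins vs distinct architectures."""
    if len(summaries) < 3:
        raise UndefinedMetricError("correlation requires at least 3 genomes")
    x = [s.n_ca_proteins for s in summaries]
    y = [s.n_ca_archs for s in summaries]
    if len(set(x)) < 2 or len(set(y)) < 2:
        raise UndefinedMetricError("correlation undefined: zero variance on an axis")
    return float(stats.pearsonr(x, y).statistic)


def superfamily_occurrence_matrix(
    genomes: Iterable[GenomeTable], registry: CaBindingRegistry
) -> pd.DataFrame:
    """Genome × registry-superfamily matrix of per-protein occurrence counts."""
    columns = sorted(registry.id_set)
    rows = {}
    for table in genomes:
        counts = summarize_genome(table, registry).superfamily_counts
        rows[table.genome_id] = [counts[s] for s in columns]
    return pd.DataFrame.from_dict(rows, orient="index", columns=columns).rename_axis("genome_id")


def summaries_frame(summaries: Sequence[GenomeRepertoireSummary]) -> pd.DataFrame:
    """Tabulate per-genome summaries with the derived ratios for TSV export.

    Genomes where a ratio is undefined get an empty cell and a logged note
    rather than being imputed.
    """
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "genome_id": s.genome_id,
            "taxon_group": s.taxon_group,
            "total_gene_count": s.total_gene_count,
            "n_proteins_total": s.n_proteins_total,
            "n_archs_total": s.n_archs_total,
            "n_ca_proteins": s.n_ca_proteins,
            "n_ca_archs": s.n_ca_archs,
        }
        try:
            row["diversity_fraction"] = diversity_fraction(s)
        except UndefinedMetricError as exc:
            logger.warning("dropping diversity_fraction: %s", exc)
            row["diversity_fraction"] = None
        try:
            row["redundancy_ratio"] = redundancy_ratio(s)
        except UndefinedMetricError as exc:
            logger.warning("dropping redundancy_ratio: %s", exc)
            row["redundancy_ratio"] = None
        rows.append(row)
    return pd.DataFrame(rows)
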