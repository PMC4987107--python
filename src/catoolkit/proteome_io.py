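"""Per-genome proteome architecture tables and genome metadata.

A proteome table is a TSV with header ``protein_id<TAB>architecture`` holding
one row per annotated protein. Proteins with no structural annotation are
simply absent (domain annotation typically covers ~70% of a eukaryote
proteome); totals are therefore over annotated proteins, with the full gene
count optionally carried in a metadata table.

The genome id comes from the filename (``<genome_id>.tsv``); an optional
metadata TSV ``genome_id<TAB>taxon_group<TAB>total_gene_count`` supplies a
taxon label and the genome size in genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Union

from .core_model import ArchitectureError, DomainArchitecture, format_architecture, parse_architecture

PROTEOME_HEADER = ("protein_id", "architecture")
METADATA_HEADER = ("genome_id", "taxon_group", "total_gene_count")


class ProteomeTableError(ValueError):
    """Raised for malformed proteome or metadata tables."""


@dataclass(frozen=True)
class ProteomeRecord:
    protein_id: str
    architecture: DomainArchitecture

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ProteomeTableError("empty protein_id")


@dataclass(frozen=True)
class GenomeMetadata:
    genome_id: str
    taxon_group: str = "unknown"
    total_gene_count: Optional[int] = None


@dataclass(frozen=True)
class GenomeTable:
    """One genome's annotated proteome: ordered records, unique protein ids."""

    genome_id: str
    records: tuple[ProteomeRecord, ...] = ()
    taxon_group: str = "unknown"
    total_gene_count: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.genome_id:
            raise ProteomeTableError("empty genome_id")
        seen: set[str] = set()
        for rec in self.records:
            if rec.protein_id in seen:
                raise ProteomeTableError(
                    f"genome {self.genome_id!r}: duplicate protein_id {rec.protein_id!r}"
                )
            seen.add(rec.protein_id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def architectures(self) -> tuple[DomainArchitecture, ...]:
        return tuple(r.architecture for r in self.records)

    def distinct_architectures(self) -> set[DomainArchitecture]:
        return set(self.architectures)

    def architecture_of(self, protein_id: str) -> Optional[DomainArchitecture]:
        for rec in self.records:
            if rec.protein_id == protein_id:
                return rec.architecture
        return None


def _read_lines(path: Path) -> list[str]:
    # tolerate CRLF and a missing trailing newline
    text = path.read_text(encoding="utf-8")
    return [ln.rstrip("\r") for ln in text.split("\n") if ln.rstrip("\r") != ""]


def read_genome_table(
    path: Union[str, Path],
    *,
    genome_id: Optional[str] = None,
    metadata: Optional[dict[str, GenomeMetadata]] = None,
    lenient: bool = False,
    dropped: Optional[list[tuple[str, int, str]]] = None,
) -> GenomeTable:
    """Read one proteome TSV; genome id defaults to the filename stem.

    Architecture parsing is strict (delegated to
    :func:`~catoolkit.core_model.parse_architecture`); any malformed row or a
    duplicated protein id raises :class:`ProteomeTableError` with row context.
    With ``lenient=True`` bad rows are skipped instead, logged, and appended
    to ``dropped`` as ``(file, line, reason)`` when a collector is passed.
    """
    import logging

    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    lines = _read_lines(path)
    if not lines:
        raise ProteomeTableError(f"{path}: empty file (expected a header line)")
    header = tuple(lines[0].split("\t"))
    if header != PROTEOME_HEADER:
        raise ProteomeTableError(
            f"{path}: bad header {header!r}, expected {PROTEOME_HEADER!r}"
        )

    def bad_row(lineno: int, reason: str) -> None:
        if not lenient:
            raise ProteomeTableError(f"{path}:{lineno}: {reason}")
        logging.getLogger(__name__).warning("%s:%d: dropped row: %s", path, lineno, reason)
        if dropped is not None:
            dropped.append((str(path), lineno, reason))

    records: list[ProteomeRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 2:
            bad_row(lineno, f"expected 2 columns, got {len(fields)}")
            continue
        protein_id, arch_str = fields[0].strip(), fields[1]
        if not protein_id:
            bad_row(lineno, "empty protein_id")
            continue
        if protein_id in seen:
            bad_row(lineno, f"duplicate protein_id {protein_id!r}")
            continue
        try:
            arch = parse_architecture(arch_str)
        except ArchitectureError as exc:
            bad_row(lineno, str(exc))
            continue
        seen.add(protein_id)
        records.append(ProteomeRecord(protein_id, arch))
    table = GenomeTable(gid, tuple(records))
    if metadata and gid in metadata:
        meta = metadata[gid]
        table = replace(
            table, taxon_group=meta.taxon_group, total_gene_count=meta.total_gene_count
        )
    return table


def write_genome_table(table: GenomeTable, path: Union[str, Path]) -> Path:
    """Write one proteome TSV in canonical form; round-trips bit-exactly."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PROTEOME_HEADER) + "\n")
        for rec in table.records:
            fh.write(f"{rec.protein_id}\t{format_architecture(rec.architecture)}\n")
    return path


def read_metadata(path: Union[str, Path]) -> dict[str, GenomeMetadata]:
    """Read the optional genome metadata TSV keyed by genome_id."""
    path = Path(path)
    lines = _read_lines(path)
    if not lines:
        raise ProteomeTableError(f"{path}: empty metadata file")
    header = tuple(lines[0].split("\t"))
    if header != METADATA_HEADER:
        raise ProteomeTableError(
            f"{path}: bad metadata header {header!r}, expected {METADATA_HEADER!r}"
        )
    out: dict[str, GenomeMetadata] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ProteomeTableError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
        gid, group, count_s = (f.strip() for f in fields)
        if not gid:
            raise ProteomeTableError(f"{path}:{lineno}: empty genome_id")
        if gid in out:
            raise ProteomeTableError(f"{path}:{lineno}: duplicate genome_id {gid!r}")
        count: Optional[int] = None
        if count_s:
            if not count_s.isdigit():
                raise ProteomeTableError(
                    f"{path}:{lineno}: non-integer total_gene_count {count_s!r}"
                )
            count = int(count_s)
        out[gid] = GenomeMetadata(gid, group or "unknown", count)
    return out


def write_metadata(metadata: Iterable[GenomeMetadata], path: Union[str, Path]) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(METADATA_HEADER) + "\n")
        for m in metadata:
            count = "" if m.total_gene_count is None else str(m.total_gene_count)
            fh.write(f"{m.genome_id}\t{m.taxon_group}\t{count}\n")
    return path


def read_proteome_dir(
    directory: Union[str, Path],
    metadata_path: Optional[Union[str, Path]] = None,
    *,
    lenient: bool = False,
    dropped: Optional[list[tuple[str, int, str]]] = None,
) -> list[GenomeTable]:
    """Read every ``*.tsv`` proteome in a directory, sorted by genome id.

    ``metadata.tsv`` inside the directory is treated as metadata, not as a
    genome, when no explicit metadata path is given.
    """
    directory = Path(directory)
    meta: dict[str, GenomeMetadata] = {}
    implicit_meta = directory / "metadata.tsv"
    if metadata_path is not None:
        meta = read_metadata(metadata_path)
    elif implicit_meta.exists():
        meta = read_metadata(implicit_meta)
    tables = []
    for p in sorted(directory.glob("*.tsv")):
        if p.name == "metadata.tsv":
            continue
        tables.append(read_genome_table(p, metadata=meta, lenient=lenient, dropped=dropped))
    if not tables:
        raise ProteomeTableError(f"{directory}: no proteome tables found")
    return tables
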