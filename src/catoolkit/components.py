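"""Functional-component labeling of architectures and toolkit-level summaries.

Calcium signaling is organized into functional components: calcium *influx*
(channels), *efflux* (pumps/exchangers), signal *decoding* (e.g. CDPKs,
calmodulin) and signal *relay* (e.g. downstream kinases, muscle-contraction
machinery). Components are data, not code: a catalog TSV lists each
component with its category and whether performing it requires binding
calcium.

Known calcium-signaling proteins (from pathway databases and the
literature) arrive as (protein_id, genome_id, component_id) rows. Each
protein's labels are inferred onto its domain architecture; for components
that require calcium binding, architectures lacking any registry domain are
dropped. Annotations are architecture-level and global; presence is then
evaluated per genome for the minimal-toolkit and breakdown summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

from .core_model import CaBindingRegistry, DomainArchitecture, contains_ca_domain
from .proteome_io import GenomeTable, _read_lines

logger = logging.getLogger(__name__)

CATEGORIES = ("influx", "efflux", "decoding", "relay", "other")
CATALOG_HEADER = ("component_id", "category", "binds_calcium")
PCT_HEADER = ("protein_id", "genome_id", "component_id")


class ComponentError(ValueError):
    """Raised for catalog/label-table problems."""


@dataclass(frozen=True)
class ComponentLabel:
    component_id: str
    category: str
    binds_calcium: bool

    def __post_init__(self) -> None:
        if not self.component_id:
            raise ComponentError("empty component_id")
        if self.category not in CATEGORIES:
            raise ComponentError(
                f"component {self.component_id!r}: category {self.category!r} "
                f"not in {CATEGORIES}"
            )


@dataclass(frozen=True)
class ComponentCatalog:
    labels: tuple[ComponentLabel, ...]

    def __post_init__(self) -> None:
        ids = [l.component_id for l in self.labels]
        if len(ids) != len(set(ids)):
            raise ComponentError("duplicate component_id in catalog")

    def __contains__(self, component_id: str) -> bool:
        return any(l.component_id == component_id for l in self.labels)

    def __getitem__(self, component_id: str) -> ComponentLabel:
        for l in self.labels:
            if l.component_id == component_id:
                return l
        raise KeyError(component_id)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(l.component_id for l in self.labels)


@dataclass(frozen=True)
class ArchitectureAnnotation:
    """One architecture with the nonempty set of components it enables."""

    architecture: DomainArchitecture
    components: frozenset[str]

    def __post_init__(self) -> None:
        if not self.components:
            raise ComponentError(
                f"architecture {self.architecture} annotated with no components"
            )


@dataclass(frozen=True)
class ProteinComponentRow:
    protein_id: str
    genome_id: str
    component_id: str


ProteinComponentTable = tuple[ProteinComponentRow, ...]


def _parse_bool(text: str, context: str) -> bool:
    low = text.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise ComponentError(f"{context}: bad boolean {text!r}")


def load_catalog(path: Union[str, Path]) -> ComponentCatalog:
    """Load the component catalog TSV ``component_id,category,binds_calcium``."""
    path = Path(path)
    lines = _read_lines(path)
    if not lines or tuple(lines[0].split("\t")) != CATALOG_HEADER:
        raise ComponentError(f"{path}: expected header {CATALOG_HEADER!r}")
    labels = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 3:
            raise ComponentError(f"{path}:{lineno}: expected 3 columns")
        labels.append(
            ComponentLabel(
                fields[0].strip(), fields[1].strip(),
                _parse_bool(fields[2], f"{path}:{lineno}"),
            )
        )
    if not labels:
        raise ComponentError(f"{path}: empty catalog")
    return ComponentCatalog(tuple(labels))


def load_protein_components(path: Union[str, Path]) -> ProteinComponentTable:
    """Load the protein→component label TSV."""
    path = Path(path)
    lines = _read_lines(path)
    if not lines or tuple(lines[0].split("\t")) != PCT_HEADER:
        raise ComponentError(f"{path}: expected header {PCT_HEADER!r}")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 3 or not all(fields):
            raise ComponentError(f"{path}:{lineno}: expected 3 nonempty columns")
        rows.append(ProteinComponentRow(*fields))
    if not rows:
        raise ComponentError(f"{path}: empty protein component table")
    return tuple(rows)


def write_catalog(catalog: ComponentCatalog, path: Union[str, Path]) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CATALOG_HEADER) + "\n")
        for l in catalog.labels:
            fh.write(f"{l.component_id}\t{l.category}\t{str(l.binds_calcium).lower()}\n")
    return path


def write_protein_components(
    rows: Sequence[ProteinComponentRow], path: Union[str, Path]
) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(PCT_HEADER) + "\n")
        for r in rows:
            fh.write(f"{r.protein_id}\t{r.genome_id}\t{r.component_id}\n")
    return path


def default_catalog_path() -> Path:
    """Path of the packaged example component catalog."""
    from importlib import resources

    return Path(str(resources.files("catoolkit").joinpath("data/example_component_catalog.tsv")))


def load_default_catalog() -> ComponentCatalog:
    return load_catalog(default_catalog_path())


def write_annotation_map(
    annotations: Sequence[ArchitectureAnnotation], path: Union[str, Path]
) -> Path:
    """TSV export ``architecture<TAB>components`` (components semicolon-joined)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("architecture\tcomponents\n")
        for ann in sorted(annotations, key=lambda a: str(a.architecture)):
            fh.write(f"{ann.architecture}\t{';'.join(sorted(ann.components))}\n")
    return path


def build_annotation_map(
    pct: Sequence[ProteinComponentRow],
    genomes: Iterable[GenomeTable],
    catalog: ComponentCatalog,
    registry: CaBindingRegistry,
) -> list[ArchitectureAnnotation]:
    """Infer component labels from proteins onto their architectures.

    For each (protein, component) row the protein's architecture is looked up
    in its genome. Calcium-binding components only accrue to architectures
    that contain a registry domain; violating pairs are dropped with a log
    note, as are proteins that cannot be resolved. The result is the union
    over all proteins, one annotation per distinct architecture, sorted by
    architecture string for reproducible output.
    """
    genome_index: dict[str, dict[str, DomainArchitecture]] = {}
    for table in genomes:
        genome_index[table.genome_id] = {
            rec.protein_id: rec.architecture for rec in table.records
        }
    arch_components: dict[DomainArchitecture, set[str]] = {}
    for row in pct:
        if row.component_id not in catalog:
            raise ComponentError(f"unknown component_id {row.component_id!r}")
        proteins = genome_index.get(row.genome_id)
        arch = proteins.get(row.protein_id) if proteins is not None else None
        if arch is None:
            logger.warning(
                "skipping unresolvable protein %s in genome %s",
                row.protein_id, row.genome_id,
            )
            continue
        label = catalog[row.component_id]
        if label.binds_calcium and not contains_ca_domain(arch, registry):
            logger.warning(
                "dropping calcium-binding component %s for architecture %s "
                "(no calcium-binding domain)", row.component_id, arch,
            )
            continue
        arch_components.setdefault(arch, set()).add(row.component_id)
    if not arch_components:
        raise ComponentError("no architecture received any component annotation")
    return [
        ArchitectureAnnotation(a, frozenset(c))
        for a, c in sorted(arch_components.items(), key=lambda kv: str(kv[0]))
    ]


def classify_purpose(annotation: ArchitectureAnnotation, min_components: int = 2) -> str:
    """``"multi"`` iff the architecture enables >= ``min_components`` components."""
    if min_components < 2:
        raise ValueError("min_components must be >= 2")
    return "multi" if len(annotation.components) >= min_components else "single"


def count_multipurpose(annotations: Iterable[ArchitectureAnnotation], k: int = 2) -> int:
    """Number of annotated architectures enabling >= k components."""
    return sum(1 for a in annotations if len(a.components) >= k)


def component_coverage(
    annotations: Sequence[ArchitectureAnnotation], genomes: Sequence[GenomeTable]
) -> dict[str, float]:
    """Fraction of genomes containing >=1 architecture annotated with each component."""
    if not genomes:
        raise ComponentError("coverage requires at least one genome")
    comp_archs: dict[str, set[DomainArchitecture]] = {}
    for ann in annotations:
        for c in ann.components:
            comp_archs.setdefault(c, set()).add(ann.architecture)
    n = len(genomes)
    genome_sets = [g.distinct_architectures() for g in genomes]
    return {
        c: sum(1 for gs in genome_sets if gs & archs) / n
        for c, archs in sorted(comp_archs.items())
    }


def core_toolkit(
    annotations: Sequence[ArchitectureAnnotation],
    genomes: Sequence[GenomeTable],
    coverage_threshold: float = 1.0,
) -> set[str]:
    """The conserved-core components: coverage >= ``coverage_threshold``.

    At threshold 1.0 this is the minimal toolkit — components for which every
    genome has at least one annotated architecture. Antitone in the
    threshold: relaxing it can only grow the set.
    """
    if not (0.0 < coverage_threshold <= 1.0):
        raise ValueError("coverage_threshold must be in (0, 1]")
    coverage = component_coverage(annotations, genomes)
    # small epsilon so e.g. 9/10 >= 0.9 despite float representation
    eps = 1e-12
    return {c for c, f in coverage.items() if f >= coverage_threshold - eps}


def component_breakdown(
    genome: GenomeTable,
    annotations: Sequence[ArchitectureAnnotation],
    min_components: int = 2,
) -> tuple[dict[str, int], list[ArchitectureAnnotation]]:
    """Functional breakdown of the annotated architectures present in a genome.

    Returns per-component counts of distinct single-purpose architectures
    present, and the list of multipurpose annotations present. Architectures
    absent from the annotation map contribute nothing.
    """
    present = genome.distinct_architectures()
    single_counts: dict[str, int] = {}
    multi: list[ArchitectureAnnotation] = []
    for ann in annotations:
        if ann.architecture not in present:
            continue
        if classify_purpose(ann, min_components) == "multi":
            multi.append(ann)
        else:
            (comp,) = tuple(ann.components)
            single_counts[comp] = single_counts.get(comp, 0) + 1
    return single_counts, multi


def annotation_components_by_architecture(
    annotations: Iterable[ArchitectureAnnotation],
) -> Mapping[DomainArchitecture, frozenset[str]]:
    """Index annotations by architecture."""
    return {a.architecture: a.components for a in annotations}
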