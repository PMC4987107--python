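"""Domain-architecture data model and the calcium-binding superfamily registry.

A protein's *domain architecture* is the ordered (N- to C-terminal) sequence
of SCOP superfamily domains assigned along its sequence, serialized as a
comma-separated string of integer sunids with the literal ``_gap_`` marking
unannotated stretches, e.g. ``47473,_gap_,50729,56112,_gap_``.

The registry is the manually curated collection of calcium-binding SCOP
superfamilies (EF-hand, C2 domain, calcium ATPase domains, ...) that defines
which architectures count as calcium-binding: an architecture belongs to the
calcium-signaling repertoire iff at least one of its domains is in the
registry.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

GAP = "_gap_"

Token = Union[int, str]  # int sunid or the GAP literal


class ArchitectureError(ValueError):
    """Raised for malformed architecture strings."""


class RegistryError(ValueError):
    """Raised for malformed or empty registry files."""


@dataclass(frozen=True, order=True)
class SuperfamilyId:
    """A SCOP superfamily identifier (sunid), e.g. 47473 for the EF-hand."""

    sunid: int

    def __post_init__(self) -> None:
        if not isinstance(self.sunid, int) or isinstance(self.sunid, bool) or self.sunid <= 0:
            raise ValueError(f"superfamily id must be a positive integer, got {self.sunid!r}")

    def __int__(self) -> int:
        return self.sunid

    def __str__(self) -> str:
        return str(self.sunid)


@dataclass(frozen=True)
class DomainArchitecture:
    """An ordered token sequence: superfamily sunids and gap markers.

    Two architectures are equal iff their token sequences are identical,
    gaps included — ``47473`` and ``47473,_gap_`` are distinct architectures.
    """

    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ArchitectureError("architecture has no tokens")
        for t in self.tokens:
            if t == GAP:
                continue
            if not isinstance(t, int) or isinstance(t, bool) or t <= 0:
                raise ArchitectureError(f"invalid architecture token {t!r}")
        if self.domain_count == 0:
            raise ArchitectureError(
                f"architecture {format_architecture(self)!r} contains no superfamily domain"
            )

    @property
    def domains(self) -> tuple[int, ...]:
        """The sunids in N→C order, gaps skipped (repeats retained)."""
        return tuple(t for t in self.tokens if t != GAP)

    @property
    def domain_count(self) -> int:
        return sum(1 for t in self.tokens if t != GAP)

    @property
    def gap_count(self) -> int:
        return sum(1 for t in self.tokens if t == GAP)

    @property
    def source_string(self) -> str:
        return format_architecture(self)

    def __str__(self) -> str:
        return format_architecture(self)


def parse_architecture(text: str) -> DomainArchitecture:
    """Parse a SUPERFAMILY-dialect architecture string.

    Accepts comma-separated integer sunids and literal ``_gap_`` markers;
    leading/trailing whitespace (around the string and around each token) is
    stripped. Anything else — including an empty string or a string with no
    integer token — raises :class:`ArchitectureError` naming the offender.
    """
    if text is None:
        raise ArchitectureError("architecture string is None")
    stripped = text.strip()
    if not stripped:
        raise ArchitectureError("empty architecture string")
    tokens: list[Token] = []
    for raw in stripped.split(","):
        tok = raw.strip()
        if tok == GAP:
            tokens.append(GAP)
        elif tok.isdigit() and int(tok) > 0:
            tokens.append(int(tok))
        else:
            raise ArchitectureError(f"malformed architecture token {tok!r} in {text!r}")
    if all(t == GAP for t in tokens):
        raise ArchitectureError(f"architecture {text!r} contains no superfamily domain")
    return DomainArchitecture(tuple(tokens))


def format_architecture(arch: DomainArchitecture) -> str:
    """Canonical serialization: comma-separated, no spaces, ``_gap_`` literal.

    ``parse_architecture(format_architecture(a)) == a`` for every valid ``a``.
    """
    return ",".join(str(t) for t in arch.tokens)


@dataclass(frozen=True)
class RegistryEntry:
    sunid: int
    name: str
    prosite_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class CaBindingRegistry:
    """The curated calcium-binding superfamily collection.

    ``entries`` preserves the source table row-by-row (a row may legitimately
    repeat); ``id_set`` is the deduplicated set of sunids used for membership
    tests.
    """

    entries: tuple[RegistryEntry, ...]
    id_set: frozenset[int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "id_set", frozenset(e.sunid for e in self.entries))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, sunid: int) -> bool:
        return int(sunid) in self.id_set


def load_registry(path: Union[str, Path]) -> CaBindingRegistry:
    """Load a registry CSV with header ``superfamily_id,name,prosite_ids``.

    ``prosite_ids`` is semicolon-separated and may be empty. Duplicate rows
    are retained in ``entries`` but collapse in ``id_set``. A header-only
    file, a missing column, or a non-integer id is a :class:`RegistryError`
    carrying the offending row number.
    """
    path = Path(path)
    entries: list[RegistryEntry] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"superfamily_id", "name", "prosite_ids"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise RegistryError(
                f"{path}: registry header must contain {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            raw_id = (row["superfamily_id"] or "").strip()
            if not raw_id.isdigit() or int(raw_id) <= 0:
                raise RegistryError(f"{path}:{lineno}: non-integer superfamily_id {raw_id!r}")
            name = (row["name"] or "").strip()
            if not name:
                raise RegistryError(f"{path}:{lineno}: empty superfamily name")
            prosites = tuple(
                p.strip() for p in (row["prosite_ids"] or "").split(";") if p.strip()
            )
            entries.append(RegistryEntry(int(raw_id), name, prosites))
    if not entries:
        raise RegistryError(f"{path}: registry contains no entries")
    return CaBindingRegistry(tuple(entries))


def default_registry_path() -> Path:
    """Path of the packaged calcium-binding superfamily registry."""
    return Path(str(resources.files("catoolkit").joinpath("data/ca_binding_superfamilies.csv")))


def load_default_registry() -> CaBindingRegistry:
    """The packaged curated registry (31 entries, 30 distinct sunids)."""
    return load_registry(default_registry_path())


def contains_ca_domain(arch: DomainArchitecture, registry: CaBindingRegistry) -> bool:
    """True iff any domain of ``arch`` is a registry calcium-binding superfamily."""
    return any(t in registry.id_set for t in arch.tokens if t != GAP)


def write_registry(registry: CaBindingRegistry, path: Union[str, Path]) -> Path:
    """Write a registry CSV in the canonical column order."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["superfamily_id", "name", "prosite_ids"])
        for e in registry.entries:
            writer.writerow([e.sunid, e.name, ";".join(e.prosite_ids)])
    return path


def build_registry(rows: Iterable[tuple[int, str, Iterable[str]]]) -> CaBindingRegistry:
    """Construct a registry from in-memory ``(sunid, name, prosite_ids)`` rows."""
    entries = tuple(RegistryEntry(int(s), str(n), tuple(p)) for s, n, p in rows)
    if not entries:
        raise RegistryError("registry contains no entries")
    return CaBindingRegistry(entries)
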