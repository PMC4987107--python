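"""End-to-end orchestration: metrics, components, ancestral stages, manifest.

The pipeline is a pure function of its input files and configuration:
identical inputs produce byte-identical outputs (the manifest records a
SHA-256 per output file so reruns can be hash-verified). Strict parsing is
the default; lenient mode downgrades malformed proteome rows to warnings and
writes a dropped-row report instead of aborting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import __version__
from .ancestral import (
    branch_events,
    dollo_reconstruct,
    presence_from_genomes,
    read_tree,
    treemap_tables,
    write_branch_events,
    write_state_matrix,
)
from .components import (
    build_annotation_map,
    component_breakdown,
    component_coverage,
    core_toolkit,
    count_multipurpose,
    load_catalog,
    load_protein_components,
    write_annotation_map,
)
from .core_model import load_registry
from .proteome_io import read_proteome_dir
from .repertoire_metrics import (
    UndefinedMetricError,
    abundance_diversity_correlation,
    summaries_frame,
    summarize_genome,
    superfamily_occurrence_matrix,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a stage cannot run on the given inputs."""


@dataclass
class RunConfig:
    tree: Optional[Path] = None
    proteomes: Optional[Path] = None
    registry: Optional[Path] = None
    catalog: Optional[Path] = None
    components: Optional[Path] = None
    out: Path = Path("catoolkit-out")
    metadata: Optional[Path] = None
    min_multi: int = 2
    core_thresholds: tuple[float, ...] = (1.0, 0.9)
    lenient: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "RunConfig":
        """Load a YAML config; keyword overrides win over file values.

        Recognized keys mirror the field names (paths as strings,
        ``core_thresholds`` as a list of floats).
        """
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        return cls._coerce(merged)

    @classmethod
    def _coerce(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key in ("tree", "proteomes", "registry", "catalog", "components", "out", "metadata"):
            if kwargs.get(key) is not None:
                kwargs[key] = Path(kwargs[key])
        if "core_thresholds" in kwargs and kwargs["core_thresholds"] is not None:
            kwargs["core_thresholds"] = tuple(float(t) for t in kwargs["core_thresholds"])
        return cls(**kwargs)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise PipelineError(f"config is missing required path {name!r}")
            if not Path(value).exists():
                raise PipelineError(f"{name} path does not exist: {value}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> Path:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n", encoding="utf-8")
    return path


def _load_inputs(config: RunConfig):
    config.require("proteomes", "registry")
    registry = load_registry(config.registry)
    dropped: list[tuple[str, int, str]] = []
    genomes = read_proteome_dir(
        config.proteomes,
        metadata_path=config.metadata,
        lenient=config.lenient,
        dropped=dropped,
    )
    return registry, genomes, dropped


def _write_dropped(dropped: Sequence[tuple[str, int, str]], out: Path) -> Optional[Path]:
    if not dropped:
        return None
    path = out / "dropped_rows.tsv"
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("file\tline\treason\n")
        for f, line, reason in dropped:
            fh.write(f"{f}\t{line}\t{reason}\n")
    return path


def run_metrics(config: RunConfig) -> dict[str, Path]:
    """Per-genome summaries, occurrence matrix, and cross-genome statistics."""
    config.out.mkdir(parents=True, exist_ok=True)
    registry, genomes, dropped = _load_inputs(config)
    logger.info("metrics stage: %d genomes", len(genomes))
    summaries = [summarize_genome(g, registry) for g in genomes]
    outputs: dict[str, Path] = {}

    frame = summaries_frame(summaries)
    summary_path = config.out / "genome_summaries.tsv"
    frame.to_csv(summary_path, sep="\t", index=False)
    outputs["genome_summaries"] = summary_path

    matrix = superfamily_occurrence_matrix(genomes, registry)
    matrix_path = config.out / "occurrence_matrix.tsv"
    matrix.to_csv(matrix_path, sep="\t")
    outputs["occurrence_matrix"] = matrix_path

    stats: dict = {"n_genomes": len(summaries)}
    usable = [s for s in summaries if s.n_ca_proteins > 0]
    stats["n_genomes_with_ca"] = len(usable)
    try:
        stats["abundance_diversity_pearson_r"] = abundance_diversity_correlation(usable)
    except UndefinedMetricError as exc:
        logger.warning("correlation undefined: %s", exc)
        stats["abundance_diversity_pearson_r"] = None
        stats["note"] = str(exc)
    outputs["cross_genome_stats"] = _write_json(stats, config.out / "cross_genome_stats.json")

    report = _write_dropped(dropped, config.out)
    if report:
        outputs["dropped_rows"] = report
    return outputs


def run_components(config: RunConfig) -> dict[str, Path]:
    """Annotation map, core-toolkit sensitivity sweep, per-genome breakdowns."""
    config.out.mkdir(parents=True, exist_ok=True)
    config.require("catalog", "components")
    registry, genomes, dropped = _load_inputs(config)
    catalog = load_catalog(config.catalog)
    pct = load_protein_components(config.components)
    annotations = build_annotation_map(pct, genomes, catalog, registry)
    outputs: dict[str, Path] = {}

    outputs["annotation_map"] = write_annotation_map(
        annotations, config.out / "annotation_map.tsv"
    )

    coverage = component_coverage(annotations, genomes)
    report = {
        "n_genomes": len(genomes),
        "n_annotated_architectures": len(annotations),
        "n_multipurpose": count_multipurpose(annotations, config.min_multi),
        "n_multipurpose_3plus": count_multipurpose(annotations, 3),
        "component_coverage": coverage,
        "core_by_threshold": {
            f"{t:g}": sorted(core_toolkit(annotations, genomes, t))
            for t in config.core_thresholds
        },
    }
    outputs["core_toolkit"] = _write_json(report, config.out / "core_toolkit.json")

    breakdown_path = config.out / "component_breakdown.tsv"
    multi_path = config.out / "multipurpose_architectures.tsv"
    with breakdown_path.open("w", encoding="utf-8", newline="\n") as bfh, \
            multi_path.open("w", encoding="utf-8", newline="\n") as mfh:
        bfh.write("genome_id\tcomponent_id\tn_single_purpose\n")
        mfh.write("genome_id\tarchitecture\tcomponents\n")
        for genome in genomes:
            singles, multi = component_breakdown(genome, annotations, config.min_multi)
            for comp in sorted(singles):
                bfh.write(f"{genome.genome_id}\t{comp}\t{singles[comp]}\n")
            for ann in sorted(multi, key=lambda a: str(a.architecture)):
                mfh.write(
                    f"{genome.genome_id}\t{ann.architecture}\t"
                    f"{';'.join(sorted(ann.components))}\n"
                )
    outputs["component_breakdown"] = breakdown_path
    outputs["multipurpose_architectures"] = multi_path

    report_path = _write_dropped(dropped, config.out)
    if report_path:
        outputs["dropped_rows"] = report_path
    return outputs


def run_ancestral(config: RunConfig) -> dict[str, Path]:
    """Dollo states, branch events, and treemap tables on the species tree."""
    config.out.mkdir(parents=True, exist_ok=True)
    config.require("tree", "catalog", "components")
    registry, genomes, dropped = _load_inputs(config)
    tree = read_tree(config.tree)
    genome_ids = {g.genome_id for g in genomes}
    leaf_ids = set(tree.leaf_labels)
    if genome_ids != leaf_ids:
        raise PipelineError(
            "tree leaves and genomes disagree: "
            f"only-in-tree={sorted(leaf_ids - genome_ids)[:5]}, "
            f"only-in-proteomes={sorted(genome_ids - leaf_ids)[:5]}"
        )
    catalog = load_catalog(config.catalog)
    pct = load_protein_components(config.components)
    annotations = build_annotation_map(pct, genomes, catalog, registry)

    presence = presence_from_genomes(genomes)
    states = dollo_reconstruct(tree, presence)
    events = branch_events(tree, states)
    outputs: dict[str, Path] = {}
    outputs["ancestral_states"] = write_state_matrix(states, config.out / "ancestral_states.tsv")
    outputs["branch_events"] = write_branch_events(events, config.out / "branch_events.tsv")
    records = treemap_tables(states, annotations, config.min_multi)
    outputs["treemap_tables"] = _write_json(
        {"nodes": records}, config.out / "treemap_tables.json"
    )
    report_path = _write_dropped(dropped, config.out)
    if report_path:
        outputs["dropped_rows"] = report_path
    return outputs


def run_all(config: RunConfig) -> dict[str, Path]:
    """All three stages plus a manifest with input paths and output hashes."""
    outputs: dict[str, Path] = {}
    outputs.update(run_metrics(config))
    outputs.update(run_components(config))
    outputs.update(run_ancestral(config))
    manifest = {
        "package_version": __version__,
        "inputs": {
            name: str(getattr(config, name))
            for name in ("tree", "proteomes", "registry", "catalog", "components", "metadata")
            if getattr(config, name) is not None
        },
        "parameters": {
            "min_multi": config.min_multi,
            "core_thresholds": list(config.core_thresholds),
            "lenient": config.lenient,
        },
        "outputs": {
            name: {"path": str(Path(p).relative_to(config.out)), "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    manifest_path = _write_json(manifest, config.out / "manifest.json")
    outputs["manifest"] = manifest_path
    return outputs
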