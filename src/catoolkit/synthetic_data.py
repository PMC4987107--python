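"""Simulate species trees and evolving architecture repertoires with truth.

The generator plants a complete gain/loss history for every architecture on
a random rooted species tree, then materializes leaf proteomes (with
per-genome copy numbers), a component catalog labeling, and a
machine-readable :class:`SimulationTruth`, so every downstream stage —
repertoire metrics, component annotation, Dollo reconstruction — can be
validated against known ground truth without any external database.

The dynamics mirror how domain-architecture repertoires actually evolve: an
architecture is created once (on one node of the tree), is inherited by
descendants, may be lost on branches, and is duplicated within genomes to a
per-genome copy number. Calcium-binding architectures carry at least one
registry superfamily token; the remaining tokens come from a disjoint
"background" sunid range so registry membership is unambiguous.

In ``terminal_losses_only`` mode losses are confined to terminal branches
and draws are additionally rejected unless the history is exactly
recoverable from the leaves under the single-gain/minimal-loss model (every
surviving internal node keeps a surviving descendant leaf, and survivors
span at least two children of the gain node). This mode exists to produce
histories whose reconstruction can be checked node-for-node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .ancestral import SpeciesTree, TreeNode, tree_from_newick
from .components import (
    ComponentCatalog,
    ProteinComponentRow,
    ProteinComponentTable,
    write_catalog,
    write_protein_components,
)
from .core_model import (
    GAP,
    CaBindingRegistry,
    DomainArchitecture,
    format_architecture,
    write_registry,
)
from .proteome_io import (
    GenomeMetadata,
    GenomeTable,
    ProteomeRecord,
    write_genome_table,
    write_metadata,
)


class SimulationError(ValueError):
    """Raised for invalid simulation configurations or impossible draws."""


# Background (non-calcium) sunid range; disjoint from every registry id.
_BACKGROUND_ID_LOW = 200000
_BACKGROUND_ID_HIGH = 210000


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the repertoire simulator.

    copy_number_law: ``("constant", k)``, ``("poisson", lam)`` (shifted,
    1 + Poisson(lam)) or ``("geometric", p)`` (support >= 1).
    component_count_law: probabilities of an architecture enabling
    1, 2, ... components.
    """

    n_leaves: int = 20
    seed: int = 0
    n_architectures: int = 200
    fraction_ca: float = 0.3
    gain_placement: str = "uniform"  # "uniform" | "root" | "root-biased"
    loss_prob_per_branch: float = 0.05
    copy_number_law: tuple = ("poisson", 1.0)
    component_count_law: tuple[float, ...] = (0.75, 0.18, 0.07)
    terminal_losses_only: bool = False
    gap_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise SimulationError("n_leaves must be >= 2")
        if self.n_architectures < 1:
            raise SimulationError("n_architectures must be >= 1")
        if not (0.0 <= self.fraction_ca <= 1.0):
            raise SimulationError("fraction_ca must be in [0, 1]")
        if not (0.0 <= self.loss_prob_per_branch < 1.0):
            raise SimulationError("loss_prob_per_branch must be in [0, 1)")
        if not (0.0 <= self.gap_prob < 1.0):
            raise SimulationError("gap_prob must be in [0, 1)")
        if self.gain_placement not in {"uniform", "root", "root-biased"}:
            raise SimulationError(f"unknown gain_placement {self.gain_placement!r}")
        law = self.copy_number_law
        if len(law) != 2 or law[0] not in {"constant", "poisson", "geometric"}:
            raise SimulationError(f"unknown copy_number_law {law!r}")
        probs = self.component_count_law
        if not probs or any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise SimulationError("component_count_law must be probabilities summing to 1")


@dataclass(frozen=True)
class SimulationTruth:
    """Planted history keyed by canonical architecture strings."""

    states: dict[str, frozenset[str]]  # arch -> node ids truly present
    gain_node: dict[str, str]
    loss_branches: dict[str, frozenset[tuple[str, str]]]
    component_map: dict[str, frozenset[str]]
    copy_numbers: dict[tuple[str, str], int]  # (genome_id, arch) -> copies
    ca_flags: dict[str, bool]

    def loss_count(self, arch: str) -> int:
        return len(self.loss_branches[arch])


# ---------------------------------------------------------------------------
# Tree simulation


def simulate_tree(n_leaves: int, seed: int) -> SpeciesTree:
    """Random rooted bifurcating topology by uniform edge attachment.

    Starts from a two-leaf tree and attaches each further leaf to an edge
    drawn uniformly at random. Leaves are named ``G0001`` ... in order of
    introduction; the result is byte-deterministic under the seed.
    """
    if n_leaves < 2:
        raise SimulationError("n_leaves must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # lightweight mutable topology: each node is a list of children; leaves are strings
    root: list = ["G0001", "G0002"]

    def edges(node: list) -> list[tuple[list, int]]:
        out = []
        for i, child in enumerate(node):
            out.append((node, i))
            if isinstance(child, list):
                out.extend(edges(child))
        return out

    for k in range(3, n_leaves + 1):
        es = edges(root)
        parent, idx = es[int(rng.integers(0, len(es)))]
        parent[idx] = [parent[idx], f"G{k:04d}"]

    def render(node) -> str:
        if isinstance(node, str):
            return node
        return "(" + ",".join(render(c) for c in node) + ")"

    return tree_from_newick(render(root) + ";")


# ---------------------------------------------------------------------------
# Repertoire evolution


def _draw_architecture(
    rng: np.random.Generator,
    is_ca: bool,
    registry: CaBindingRegistry,
    gap_prob: float,
    taken: set[str],
) -> DomainArchitecture:
    registry_ids = sorted(registry.id_set)
    for _ in range(200):
        n_dom = int(rng.integers(1, 5))
        domains = [int(x) for x in rng.integers(_BACKGROUND_ID_LOW, _BACKGROUND_ID_HIGH, n_dom)]
        if is_ca:
            pos = int(rng.integers(0, n_dom))
            domains[pos] = registry_ids[int(rng.integers(0, len(registry_ids)))]
        tokens: list = []
        if rng.random() < gap_prob:
            tokens.append(GAP)
        for d in domains:
            tokens.append(d)
            if rng.random() < gap_prob:
                tokens.append(GAP)
        arch = DomainArchitecture(tuple(tokens))
        key = format_architecture(arch)
        if key not in taken:
            taken.add(key)
            return arch
    raise SimulationError("could not draw a unique architecture (universe exhausted?)")


def _draw_gain_node(
    rng: np.random.Generator, tree: SpeciesTree, placement: str
) -> TreeNode:
    internals = [n for n in tree.nodes if not n.is_leaf]
    if placement == "root":
        return tree.root
    if placement == "root-biased" and rng.random() < 0.5:
        return tree.root
    return internals[int(rng.integers(0, len(internals)))]


def _recoverable(tree: SpeciesTree, gain: TreeNode, survivor_mask: int) -> bool:
    """True iff Dollo reconstruction from the surviving leaves equals the
    terminal-loss truth node-for-node."""
    spanning = sum(1 for c in gain.children if c.leaf_mask & survivor_mask)
    if spanning < 2:
        return False
    stack = list(gain.children)
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            if not (node.leaf_mask & survivor_mask):
                return False
            stack.extend(node.children)
    return True


def _simulate_history(
    rng: np.random.Generator, tree: SpeciesTree, config: SimulationConfig
) -> tuple[TreeNode, set[str], frozenset[tuple[str, str]]]:
    """Draw gain node and losses until >=1 leaf survives (and, in terminal-loss
    mode, until the history is exactly recoverable). Returns
    (gain, present node ids, loss branches)."""
    for _ in range(10000):
        gain = _draw_gain_node(rng, tree, config.gain_placement)
        present: set[str] = {gain.node_id}
        losses: set[tuple[str, str]] = set()
        survivor_mask = 0
        stack = list(gain.children)
        parent_of = {c.node_id: gain.node_id for c in gain.children}
        while stack:
            node = stack.pop()
            loss_allowed = node.is_leaf or not config.terminal_losses_only
            if loss_allowed and rng.random() < config.loss_prob_per_branch:
                losses.add((parent_of[node.node_id], node.node_id))
                continue
            present.add(node.node_id)
            if node.is_leaf:
                survivor_mask |= node.leaf_mask
            for c in node.children:
                parent_of[c.node_id] = node.node_id
                stack.append(c)
        if survivor_mask == 0:
            continue
        if config.terminal_losses_only and not _recoverable(tree, gain, survivor_mask):
            continue
        return gain, present, frozenset(losses)
    raise SimulationError("failed to draw a surviving history; lower loss_prob_per_branch")


def _draw_copies(rng: np.random.Generator, law: tuple) -> int:
    name, param = law
    if name == "constant":
        return int(param)
    if name == "poisson":
        return 1 + int(rng.poisson(param))
    return int(rng.geometric(param))


def simulate_repertoire_evolution(
    tree: SpeciesTree,
    config: SimulationConfig,
    registry: CaBindingRegistry,
    catalog: ComponentCatalog,
) -> tuple[list[GenomeTable], ProteinComponentTable, SimulationTruth]:
    """Evolve ``n_architectures`` characters on the tree and build leaf genomes.

    Every architecture gets its own deterministic random substream derived
    from ``(seed, architecture index)``, so outputs are reproducible
    regardless of evaluation order. Component labels are attached to one
    representative protein per (architecture, genome); calcium-binding
    components are only planted on calcium-binding architectures so the
    emitted labels all survive annotation filtering.
    """
    # calcium architectures may take any component; others only those that do
    # not require calcium binding (so every planted label survives filtering)
    ca_components = sorted(l.component_id for l in catalog.labels)
    nonca_components = sorted(
        l.component_id for l in catalog.labels if not l.binds_calcium
    )
    if not nonca_components and config.fraction_ca < 1.0:
        raise SimulationError(
            "catalog has no calcium-independent component for non-calcium architectures"
        )

    n_ca = round(config.fraction_ca * config.n_architectures)
    taken: set[str] = set()
    arch_list: list[DomainArchitecture] = []
    truth_states: dict[str, frozenset[str]] = {}
    truth_gain: dict[str, str] = {}
    truth_losses: dict[str, frozenset[tuple[str, str]]] = {}
    component_map: dict[str, frozenset[str]] = {}
    copy_numbers: dict[tuple[str, str], int] = {}
    ca_flags: dict[str, bool] = {}

    leaf_archs: dict[str, list[tuple[DomainArchitecture, int]]] = {
        l: [] for l in tree.leaf_labels
    }

    for j in range(config.n_architectures):
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(j,)))
        is_ca = j < n_ca
        arch = _draw_architecture(rng, is_ca, registry, config.gap_prob, taken)
        key = format_architecture(arch)
        gain, present, losses = _simulate_history(rng, tree, config)
        truth_states[key] = frozenset(present)
        truth_gain[key] = gain.node_id
        truth_losses[key] = losses
        ca_flags[key] = is_ca

        pool = ca_components if is_ca else nonca_components
        n_comp = 1 + int(
            rng.choice(len(config.component_count_law), p=list(config.component_count_law))
        )
        n_comp = min(n_comp, len(pool))
        comps = sorted(rng.choice(pool, size=n_comp, replace=False).tolist())
        component_map[key] = frozenset(comps)

        for leaf in tree.leaf_labels:
            if leaf in present:
                copies = _draw_copies(rng, config.copy_number_law)
                copy_numbers[(leaf, key)] = copies
                leaf_archs[leaf].append((arch, j))

    genomes: list[GenomeTable] = []
    pct_rows: list[ProteinComponentRow] = []
    for leaf in tree.leaf_labels:
        records: list[ProteomeRecord] = []
        for arch, j in leaf_archs[leaf]:
            key = format_architecture(arch)
            for i in range(copy_numbers[(leaf, key)]):
                pid = f"{leaf}_A{j:05d}_{i}"
                records.append(ProteomeRecord(pid, arch))
                if i == 0:
                    for comp in sorted(component_map[key]):
                        pct_rows.append(ProteinComponentRow(pid, leaf, comp))
        genomes.append(GenomeTable(leaf, tuple(records), taxon_group="synthetic"))

    truth = SimulationTruth(
        states=truth_states,
        gain_node=truth_gain,
        loss_branches=truth_losses,
        component_map=component_map,
        copy_numbers=copy_numbers,
        ca_flags=ca_flags,
    )
    return genomes, tuple(pct_rows), truth


# ---------------------------------------------------------------------------
# Dataset emission


def truth_to_json(truth: SimulationTruth) -> dict:
    """JSON-serializable form of the truth (schema documented in docs/methods.md)."""
    return {
        "states": {a: sorted(nodes) for a, nodes in sorted(truth.states.items())},
        "gain_node": dict(sorted(truth.gain_node.items())),
        "loss_branches": {
            a: sorted(list(b) for b in branches)
            for a, branches in sorted(truth.loss_branches.items())
        },
        "component_map": {a: sorted(c) for a, c in sorted(truth.component_map.items())},
        "copy_numbers": {
            f"{g}\t{a}": n for (g, a), n in sorted(truth.copy_numbers.items())
        },
        "ca_flags": dict(sorted(truth.ca_flags.items())),
    }


def emit_dataset(
    tree: SpeciesTree,
    genomes: list[GenomeTable],
    pct: ProteinComponentTable,
    truth: SimulationTruth,
    registry: CaBindingRegistry,
    catalog: ComponentCatalog,
    directory: Union[str, Path],
) -> dict[str, Path]:
    """Write the complete synthetic dataset; byte-identical under a fixed seed.

    Layout: ``proteomes/<genome>.tsv`` + ``proteomes/metadata.tsv``,
    ``tree.nwk``, ``registry.csv``, ``catalog.tsv``,
    ``protein_components.tsv``, ``truth.json``.
    """
    directory = Path(directory)
    proteome_dir = directory / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for table in genomes:
        paths[f"proteome:{table.genome_id}"] = write_genome_table(
            table, proteome_dir / f"{table.genome_id}.tsv"
        )
    paths["metadata"] = write_metadata(
        [
            GenomeMetadata(t.genome_id, t.taxon_group, len(t.records))
            for t in genomes
        ],
        proteome_dir / "metadata.tsv",
    )
    tree_path = directory / "tree.nwk"
    tree_path.write_text(tree.to_newick() + "\n", encoding="utf-8")
    paths["tree"] = tree_path
    paths["registry"] = write_registry(registry, directory / "registry.csv")
    paths["catalog"] = write_catalog(catalog, directory / "catalog.tsv")
    paths["protein_components"] = write_protein_components(
        pct, directory / "protein_components.tsv"
    )
    truth_path = directory / "truth.json"
    truth_path.write_text(
        json.dumps(truth_to_json(truth), indent=1, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    paths["truth"] = truth_path
    return paths


def simulate_dataset(
    config: SimulationConfig,
    registry: CaBindingRegistry,
    catalog: ComponentCatalog,
) -> tuple[SpeciesTree, list[GenomeTable], ProteinComponentTable, SimulationTruth]:
    """Convenience wrapper: tree + repertoire evolution in one call."""
    tree = simulate_tree(config.n_leaves, config.seed)
    genomes, pct, truth = simulate_repertoire_evolution(tree, config, registry, catalog)
    return tree, genomes, pct, truth
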