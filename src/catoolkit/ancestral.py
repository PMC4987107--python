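"""Species-tree handling and Dollo-parsimony ancestral repertoires.

Each domain architecture is treated as a Dollo character on a rooted species
tree: a multidomain architecture is assumed to arise exactly once (the odds
of independently re-creating the same ordered domain combination are
negligible) and may subsequently be lost any number of times. Under that
model the most parsimonious history is fully determined by the phyletic
pattern: the single gain sits at the most recent common ancestor (MRCA) of
the possessing leaves, and an internal node below the gain is scored present
iff its subtree still retains at least one possessing leaf — which provably
minimizes the number of losses given a single gain.

The model ignores horizontal transfer, so it is meaningful for eukaryote
lineages; bacteria-heavy trees violate the single-gain assumption and their
reconstructions should be read with caution.

Per-branch gains and losses are read off the reconstructed states, and
per-node repertoires can be summarized against an architecture→component
annotation map (multipurpose counts, single-purpose composition) for
treemap-style exports and root-to-leaf lineage tracing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Optional, Sequence, Union

import dendropy

from .components import ArchitectureAnnotation, classify_purpose
from .core_model import DomainArchitecture
from .proteome_io import GenomeTable


class TreeError(ValueError):
    """Raised for invalid species trees."""


class ReconstructionError(ValueError):
    """Raised for invalid phyletic input to the reconstruction."""


@dataclass
class TreeNode:
    node_id: str
    name: Optional[str] = None
    parent: Optional["TreeNode"] = None
    children: list["TreeNode"] = field(default_factory=list)
    leaf_mask: int = 0  # bitmask over leaf indices in this node's subtree

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.node_id})"


class SpeciesTree:
    """A rooted species tree with deterministic node ids.

    Leaves are identified by their labels (the genome ids). Unnamed internal
    nodes get ids ``N<k>`` where ``k`` is the node's preorder index; named
    internal nodes (e.g. ``LECA``) keep their name as the id.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes: list[TreeNode] = []  # preorder
        stack = [root]
        while stack:
            node = stack.pop()
            self.nodes.append(node)
            stack.extend(reversed(node.children))
        self.leaves = [n for n in self.nodes if n.is_leaf]
        if len(self.leaves) < 2:
            raise TreeError("species tree must have at least 2 leaves")
        labels = [n.node_id for n in self.leaves]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels: {dupes}")
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            raise TreeError("node ids are not unique (internal name clashes a leaf or N<k> id)")
        self._by_id = {n.node_id: n for n in self.nodes}
        self.leaf_index = {leaf.node_id: i for i, leaf in enumerate(self.leaves)}
        for node in reversed(self.nodes):  # postorder accumulation
            if node.is_leaf:
                node.leaf_mask = 1 << self.leaf_index[node.node_id]
            else:
                node.leaf_mask = 0
                for c in node.children:
                    node.leaf_mask |= c.leaf_mask

    def __len__(self) -> int:
        return len(self.nodes)

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._by_id[node_id]
        except KeyError:
            raise TreeError(f"unknown node id {node_id!r}") from None

    @property
    def leaf_labels(self) -> list[str]:
        return [n.node_id for n in self.leaves]

    def mask_of(self, leaf_labels: Iterable[str]) -> int:
        mask = 0
        for label in leaf_labels:
            try:
                mask |= 1 << self.leaf_index[label]
            except KeyError:
                raise ReconstructionError(f"unknown leaf label {label!r}") from None
        return mask

    def mrca(self, leaf_labels: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of the given leaves."""
        target = self.mask_of(leaf_labels)
        if target == 0:
            raise ReconstructionError("mrca of an empty leaf set")
        node = self.root
        while True:
            for child in node.children:
                if child.leaf_mask & target == target:
                    node = child
                    break
            else:
                return node

    def path_to_leaf(self, leaf_label: str) -> list[TreeNode]:
        """Root→leaf node path."""
        if leaf_label not in self.leaf_index:
            raise TreeError(f"unknown leaf {leaf_label!r}")
        node = self._by_id[leaf_label]
        path = [node]
        while node.parent is not None:
            node = node.parent
            path.append(node)
        return list(reversed(path))

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.node_id
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){node.name or ''}"

        return render(self.root) + ";"


def _from_dendropy(dtree: dendropy.Tree) -> SpeciesTree:
    if dtree.seed_node is None:
        raise TreeError("empty tree")

    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            if not label:
                raise TreeError("leaf without a label")
            return TreeNode(node_id=str(label))
        name = str(dnode.label) if dnode.label else None
        node = TreeNode(node_id="", name=name)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    # assign preorder ids to unnamed internal nodes
    counter = 0
    stack = [root]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            node.node_id = node.name if node.name else f"N{counter}"
        counter += 1
        stack.extend(reversed(node.children))
    return SpeciesTree(root)


def read_tree(path: Union[str, Path]) -> SpeciesTree:
    """Read a rooted newick species tree; polytomies are kept as-is.

    A tree explicitly flagged unrooted (``[&U]``) is rejected; plain newick
    is taken as rooted at its outermost clade, which matches how reference
    species trees are distributed.
    """
    text = Path(path).read_text(encoding="utf-8")
    return tree_from_newick(text)


def tree_from_newick(newick: str) -> SpeciesTree:
    """Parse a newick string into a :class:`SpeciesTree`."""
    if not newick.strip():
        raise TreeError("empty newick input")
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise TreeError(f"newick parse failure: {exc}") from exc
    if "[&U]" in newick or "[&u]" in newick:
        raise TreeError("tree is explicitly unrooted; a rooted species tree is required")
    return _from_dendropy(dtree)


# ---------------------------------------------------------------------------
# Dollo reconstruction

ArchKey = Hashable  # DomainArchitecture or architecture string


@dataclass(frozen=True)
class AncestralStateMatrix:
    """Presence/absence of every architecture at every node, plus gain nodes."""

    tree: SpeciesTree
    states: dict[ArchKey, frozenset[str]]  # arch -> node ids where present
    gain_node: dict[ArchKey, str]  # arch -> node id of the single gain

    def is_present(self, arch: ArchKey, node_id: str) -> bool:
        return node_id in self.states.get(arch, frozenset())

    def present_at(self, node_id: str) -> set[ArchKey]:
        return {a for a, nodes in self.states.items() if node_id in nodes}

    def loss_count(self, arch: ArchKey) -> int:
        present = self.states[arch]
        losses = 0
        for node in self.tree.nodes:
            if node.node_id in present:
                losses += sum(1 for c in node.children if c.node_id not in present)
        return losses


def presence_from_genomes(genomes: Iterable[GenomeTable]) -> dict[DomainArchitecture, set[str]]:
    """Phyletic pattern: architecture → set of genomes possessing it."""
    presence: dict[DomainArchitecture, set[str]] = {}
    for table in genomes:
        for arch in table.distinct_architectures():
            presence.setdefault(arch, set()).add(table.genome_id)
    return presence


def dollo_reconstruct(
    tree: SpeciesTree, leaf_presence: Mapping[ArchKey, Iterable[str]]
) -> AncestralStateMatrix:
    """Single-gain, minimal-loss ancestral states for every architecture.

    For each architecture the gain node is the MRCA of the possessing
    leaves; every node at or below the gain whose subtree retains a
    possessing leaf is present. Leaf states reproduce the input exactly.
    Architectures with an empty presence set or unknown leaves are rejected.
    """
    states: dict[ArchKey, frozenset[str]] = {}
    gains: dict[ArchKey, str] = {}
    for arch, leaves in leaf_presence.items():
        target = tree.mask_of(leaves)
        if target == 0:
            raise ReconstructionError(f"architecture {arch!r} is present at no leaf")
        gain = tree.mrca(leaves)
        present: set[str] = set()
        stack = [gain]
        while stack:
            node = stack.pop()
            if node.leaf_mask & target:
                present.add(node.node_id)
                stack.extend(node.children)
        states[arch] = frozenset(present)
        gains[arch] = gain.node_id
    return AncestralStateMatrix(tree, states, gains)


# ---------------------------------------------------------------------------
# Branch events

Branch = tuple[Optional[str], str]  # (parent id, child id); (None, root) = root branch


@dataclass(frozen=True)
class BranchEventMap:
    """Per-branch gained/lost architecture sets.

    The root's (virtual) incoming branch carries the gains of root-present
    architectures. Gains and losses are disjoint on every branch; each
    architecture has exactly one gain, and all its losses lie below the gain.
    """

    gains: dict[Branch, frozenset[ArchKey]]
    losses: dict[Branch, frozenset[ArchKey]]

    def branches(self) -> set[Branch]:
        return set(self.gains) | set(self.losses)


def branch_events(tree: SpeciesTree, states: AncestralStateMatrix) -> BranchEventMap:
    """Map state changes onto branches: absent→present = gain, present→absent = loss."""
    gains: dict[Branch, set[ArchKey]] = {}
    losses: dict[Branch, set[ArchKey]] = {}
    for arch, present in states.states.items():
        if tree.root.node_id in present:
            gains.setdefault((None, tree.root.node_id), set()).add(arch)
        for node in tree.nodes:
            parent_present = node.node_id in present
            for child in node.children:
                child_present = child.node_id in present
                branch = (node.node_id, child.node_id)
                if child_present and not parent_present:
                    gains.setdefault(branch, set()).add(arch)
                elif parent_present and not child_present:
                    losses.setdefault(branch, set()).add(arch)
    return BranchEventMap(
        gains={b: frozenset(s) for b, s in gains.items()},
        losses={b: frozenset(s) for b, s in losses.items()},
    )


# ---------------------------------------------------------------------------
# Repertoire summaries along the tree


def _node_repertoire(
    present: set[ArchKey],
    annotations: Sequence[ArchitectureAnnotation],
    min_components: int,
) -> dict:
    anns = [a for a in annotations if a.architecture in present]
    multi = [a for a in anns if classify_purpose(a, min_components) == "multi"]
    single = [a for a in anns if a not in multi]
    single_counts: dict[str, int] = {}
    for a in single:
        (comp,) = tuple(a.components)
        single_counts[comp] = single_counts.get(comp, 0) + 1
    return {
        "n_annotated": len(anns),
        "n_multipurpose": len(multi),
        "n_single_purpose": len(single),
        "single_purpose_counts": dict(sorted(single_counts.items())),
    }


def lineage_trajectory(
    tree: SpeciesTree,
    leaf: str,
    states: AncestralStateMatrix,
    annotations: Sequence[ArchitectureAnnotation],
    min_components: int = 2,
) -> list[dict]:
    """Root→leaf series of per-node repertoire summaries (one entry per node)."""
    path = tree.path_to_leaf(leaf)
    out = []
    for node in path:
        present = states.present_at(node.node_id)
        rec = {"node_id": node.node_id, "name": node.name}
        rec.update(_node_repertoire(present, annotations, min_components))
        out.append(rec)
    return out


def treemap_tables(
    states: AncestralStateMatrix,
    annotations: Sequence[ArchitectureAnnotation],
    min_components: int = 2,
) -> list[dict]:
    """Per-node treemap records: multipurpose share and single-purpose composition.

    ``pct_multipurpose`` is the percentage of annotated architectures present
    at the node that are multipurpose; ``single_purpose_pct`` gives each
    component's percentage of the single-purpose architectures (summing to
    100 when any are present). Nodes with no annotated architecture are
    flagged ``empty`` and carry no percentages.
    """
    records = []
    for node in states.tree.nodes:
        present = states.present_at(node.node_id)
        rep = _node_repertoire(present, annotations, min_components)
        rec: dict = {"node_id": node.node_id, "name": node.name, **rep}
        if rep["n_annotated"] == 0:
            rec["empty"] = True
            rec["pct_multipurpose"] = None
            rec["single_purpose_pct"] = {}
        else:
            rec["empty"] = False
            rec["pct_multipurpose"] = 100.0 * rep["n_multipurpose"] / rep["n_annotated"]
            n_single = rep["n_single_purpose"]
            rec["single_purpose_pct"] = {
                c: 100.0 * k / n_single for c, k in rep["single_purpose_counts"].items()
            } if n_single else {}
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Tabular I/O


def _arch_key_str(arch: ArchKey) -> str:
    return str(arch)


def write_state_matrix(states: AncestralStateMatrix, path: Union[str, Path]) -> Path:
    """TSV node × architecture 0/1 matrix, rows in preorder, columns sorted."""
    path = Path(path)
    arch_keys = sorted(states.states, key=_arch_key_str)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\t" + "\t".join(_arch_key_str(a) for a in arch_keys) + "\n")
        for node in states.tree.nodes:
            row = [node.node_id] + [
                "1" if node.node_id in states.states[a] else "0" for a in arch_keys
            ]
            fh.write("\t".join(row) + "\n")
    return path


def write_branch_events(events: BranchEventMap, path: Union[str, Path]) -> Path:
    """TSV event list ``parent,child,event,architecture``, lexicographically sorted."""
    path = Path(path)
    rows = []
    for (parent, child), archs in events.gains.items():
        rows += [(parent or "", child, "gain", _arch_key_str(a)) for a in archs]
    for (parent, child), archs in events.losses.items():
        rows += [(parent or "", child, "loss", _arch_key_str(a)) for a in archs]
    rows.sort()
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("parent\tchild\tevent\tarchitecture\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


def read_phyletic_matrix(path: Union[str, Path]) -> dict[str, set[str]]:
    """Read an architecture × genome 0/1 TSV into a presence mapping."""
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").split("\n") if ln.strip()]
    if not lines:
        raise ReconstructionError(f"{path}: empty phyletic matrix")
    header = lines[0].split("\t")
    if header[0] != "architecture":
        raise ReconstructionError(f"{path}: first column must be 'architecture'")
    genomes = header[1:]
    presence: dict[str, set[str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ReconstructionError(f"{path}:{lineno}: ragged row")
        arch = fields[0]
        possessed = {g for g, v in zip(genomes, fields[1:]) if v.strip() == "1"}
        if not possessed:
            raise ReconstructionError(f"{path}:{lineno}: architecture present in no genome")
        presence[arch] = possessed
    return presence
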