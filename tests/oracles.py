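"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's algorithms: Dollo histories are
checked by exhaustive enumeration of all single-gain state assignments, and
core-toolkit membership by direct recounting. Tree shapes are enumerated via
the Wedderburn–Etherington recursion.
"""

from __future__ import annotations

from itertools import product

from catoolkit.ancestral import SpeciesTree


def brute_dollo_min_losses(tree: SpeciesTree, possessing: set[str]) -> int:
    """Minimum loss count over every valid single-gain assignment.

    Enumerates all 2^(#internal nodes) presence assignments (leaf states are
    fixed by the pattern), keeps those with exactly one gain edge — an
    absent→present edge, counting the root's virtual incoming edge — and no
    other constraint, and returns the minimal number of present→absent edges.
    """
    internal = [n for n in tree.nodes if not n.is_leaf]
    best = None
    for bits in product((False, True), repeat=len(internal)):
        state = {n.node_id: b for n, b in zip(internal, bits)}
        for leaf in tree.leaves:
            state[leaf.node_id] = leaf.node_id in possessing
        gains = 1 if state[tree.root.node_id] else 0
        losses = 0
        for node in tree.nodes:
            for child in node.children:
                if state[child.node_id] and not state[node.node_id]:
                    gains += 1
                elif state[node.node_id] and not state[child.node_id]:
                    losses += 1
        if gains != 1:
            continue
        if best is None or losses < best:
            best = losses
    assert best is not None, "no valid single-gain assignment (empty pattern?)"
    return best


def enumerate_shape_newicks(n_leaves: int) -> list[str]:
    """All rooted bifurcating tree shapes with ``n_leaves`` leaves, as newick
    strings with leaves labeled L1.. left to right."""

    def shapes(n: int) -> list[str]:
        if n == 1:
            return ["x"]
        out = []
        for i in range(1, n // 2 + 1):
            left, right = shapes(i), shapes(n - i)
            for a_idx, a in enumerate(left):
                for b_idx, b in enumerate(right):
                    if i == n - i and b_idx < a_idx:
                        continue
                    out.append(f"({a},{b})")
        return out

    labeled = []
    for shape in shapes(n_leaves):
        counter = iter(range(1, n_leaves + 1))
        labeled.append(
            "".join(f"L{next(counter)}" if ch == "x" else ch for ch in shape) + ";"
        )
    return labeled


def brute_core_toolkit(component_archs, genome_archs, threshold: float) -> set[str]:
    """Direct coverage recount: component → set of architectures, genome →
    set of architectures present; include the component iff the genome
    fraction with an intersecting set is >= threshold (exact arithmetic via
    integer comparison)."""
    n = len(genome_archs)
    core = set()
    for comp, archs in component_archs.items():
        hits = sum(1 for present in genome_archs.values() if archs & present)
        if hits >= threshold * n - 1e-12:
            core.add(comp)
    return core
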