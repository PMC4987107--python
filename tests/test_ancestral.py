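import itertools

import pytest

from catoolkit.ancestral import (
    ReconstructionError,
    TreeError,
    branch_events,
    dollo_reconstruct,
    lineage_trajectory,
    presence_from_genomes,
    read_phyletic_matrix,
    read_tree,
    tree_from_newick,
    treemap_tables,
    write_branch_events,
    write_state_matrix,
)
from catoolkit.components import ArchitectureAnnotation
from catoolkit.core_model import parse_architecture
from conftest import make_genome
from oracles import brute_dollo_min_losses, enumerate_shape_newicks


class TestReadTree:
    def test_three_leaf_tree(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A,B),C);\n")
        tree = read_tree(path)
        assert sorted(tree.leaf_labels) == ["A", "B", "C"]
        internals = [n for n in tree.nodes if not n.is_leaf]
        assert len(internals) == 2
        assert tree.root.node_id == "N0"  # deterministic preorder id

    def test_balanced_four_leaf_tree(self):
        tree = tree_from_newick("((A,B),(C,D));")
        assert len(tree.leaves) == 4
        assert len(tree.nodes) == 7

    def test_named_internal_node_addressable(self):
        tree = tree_from_newick("((A,B)LECA,C);")
        node = tree.node("LECA")
        assert not node.is_leaf
        assert {c.node_id for c in node.children} == {"A", "B"}

    def test_polytomy_kept(self):
        tree = tree_from_newick("(A,B,C,D);")
        assert len(tree.root.children) == 4

    @pytest.mark.parametrize("newick", ["", ";", "(A);", "(A,A);", "[&U] (A,(B,C));"])
    def test_invalid_trees_rejected(self, newick):
        with pytest.raises(TreeError):
            tree_from_newick(newick)


class TestDollo:
    def test_single_leaf_architecture(self):
        tree = tree_from_newick("((A,B),C);")
        states = dollo_reconstruct(tree, {"x": {"A"}})
        assert states.states["x"] == {"A"}
        assert states.gain_node["x"] == "A"
        assert states.loss_count("x") == 0

    def test_two_distant_leaves(self):
        tree = tree_from_newick("((A,B),(C,D));")
        states = dollo_reconstruct(tree, {"x": {"A", "C"}})
        ab = tree.mrca(["A", "B"]).node_id
        cd = tree.mrca(["C", "D"]).node_id
        assert states.states["x"] == {tree.root.node_id, ab, cd, "A", "C"}
        assert states.gain_node["x"] == tree.root.node_id
        assert states.loss_count("x") == 2

    def test_universal_architecture(self):
        tree = tree_from_newick("((A,B),(C,D));")
        states = dollo_reconstruct(tree, {"x": {"A", "B", "C", "D"}})
        assert states.states["x"] == {n.node_id for n in tree.nodes}
        assert states.loss_count("x") == 0

    def test_unknown_leaf_and_empty_set_rejected(self):
        tree = tree_from_newick("((A,B),C);")
        with pytest.raises(ReconstructionError):
            dollo_reconstruct(tree, {"x": {"Z"}})
        with pytest.raises(ReconstructionError):
            dollo_reconstruct(tree, {"x": set()})

    def test_leaf_fidelity_and_single_gain_on_polytomy(self):
        tree = tree_from_newick("((A,B,C),(D,E),F);")
        pattern = {"A", "C", "E"}
        states = dollo_reconstruct(tree, {"x": pattern})
        for leaf in tree.leaf_labels:
            assert (leaf in states.states["x"]) == (leaf in pattern)
        events = branch_events(tree, states)
        n_gains = sum(1 for archs in events.gains.values() if "x" in archs)
        assert n_gains == 1

    def test_matches_brute_force_on_small_shapes(self):
        """Minimal-loss equivalence on every bifurcating shape with <= 5 leaves
        and every nonempty presence pattern (exhaustive check at 6 leaves runs
        in the acceptance suite)."""
        for n in range(2, 6):
            for newick in enumerate_shape_newicks(n):
                tree = tree_from_newick(newick)
                leaves = tree.leaf_labels
                for r in range(1, n + 1):
                    for pattern in itertools.combinations(leaves, r):
                        states = dollo_reconstruct(tree, {"x": set(pattern)})
                        assert states.loss_count("x") == brute_dollo_min_losses(
                            tree, set(pattern)
                        ), (newick, pattern)


class TestBranchEvents:
    def test_two_distant_leaves_events(self):
        tree = tree_from_newick("((A,B),(C,D));")
        states = dollo_reconstruct(tree, {"x": {"A", "C"}})
        events = branch_events(tree, states)
        root = tree.root.node_id
        assert events.gains[(None, root)] == {"x"}
        ab = tree.mrca(["A", "B"]).node_id
        cd = tree.mrca(["C", "D"]).node_id
        assert events.losses[(ab, "B")] == {"x"}
        assert events.losses[(cd, "D")] == {"x"}
        assert len(events.losses) == 2

    def test_universal_architecture_single_root_gain(self):
        tree = tree_from_newick("((A,B),C);")
        states = dollo_reconstruct(tree, {"x": {"A", "B", "C"}})
        events = branch_events(tree, states)
        assert events.gains == {(None, tree.root.node_id): frozenset({"x"})}
        assert events.losses == {}

    def test_gain_loss_disjoint_and_path_parity(self):
        tree = tree_from_newick("(((A,B),(C,D)),(E,(F,G)));")
        presence = {"x": {"A", "D", "F"}, "y": {"B", "C", "E", "G"}, "z": {"G"}}
        states = dollo_reconstruct(tree, presence)
        events = branch_events(tree, states)
        for branch in events.branches():
            assert not (events.gains.get(branch, frozenset())
                        & events.losses.get(branch, frozenset()))
        # along any root->leaf path, state flips == events on that path
        for arch in presence:
            for leaf in tree.leaf_labels:
                path = tree.path_to_leaf(leaf)
                flips = 0
                prev = False  # state above the root
                for node in path:
                    cur = node.node_id in states.states[arch]
                    flips += int(cur != prev)
                    prev = cur
                branches = [(None, path[0].node_id)] + [
                    (a.node_id, b.node_id) for a, b in zip(path, path[1:])
                ]
                n_events = sum(
                    int(arch in events.gains.get(b, frozenset()))
                    + int(arch in events.losses.get(b, frozenset()))
                    for b in branches
                )
                assert flips == n_events


def _annotated_states():
    tree = tree_from_newick("((A,B),C);")
    genomes = [
        make_genome("A", ["47473", "47473,56112", "_gap_,56112", "49562"]),
        make_genome("B", ["47473", "47473,56112"]),
        make_genome("C", ["47473"]),
    ]
    presence = presence_from_genomes(genomes)
    states = dollo_reconstruct(tree, presence)
    anns = [
        ArchitectureAnnotation(parse_architecture("47473"),
                               frozenset({"decoding-calmodulin"})),
        ArchitectureAnnotation(parse_architecture("47473,56112"),
                               frozenset({"decoding-CDPK", "relay-muscle-contraction"})),
        ArchitectureAnnotation(parse_architecture("_gap_,56112"),
                               frozenset({"relay-muscle-contraction"})),
        ArchitectureAnnotation(parse_architecture("49562"),
                               frozenset({"influx-channel"})),
    ]
    return tree, states, anns


class TestRepertoireSummaries:
    def test_trajectory_shape_and_root_repertoire(self):
        tree, states, anns = _annotated_states()
        traj = lineage_trajectory(tree, "A", states, anns)
        assert len(traj) == 3  # root, AB ancestor, leaf A
        assert [t["node_id"] for t in traj][-1] == "A"
        # root carries only 47473 (the sole architecture spanning both root children)
        assert traj[0]["n_annotated"] == 1
        assert traj[0]["n_multipurpose"] == 0
        # the A+B ancestor adds the multipurpose kinase architecture
        assert traj[1]["n_annotated"] == 2
        assert traj[1]["n_multipurpose"] == 1
        # leaf A has all four annotated architectures
        assert traj[-1]["n_annotated"] == 4
        assert traj[-1]["single_purpose_counts"] == {
            "decoding-calmodulin": 1,
            "influx-channel": 1,
            "relay-muscle-contraction": 1,
        }

    def test_trajectory_unknown_leaf(self):
        tree, states, anns = _annotated_states()
        with pytest.raises(TreeError):
            lineage_trajectory(tree, "Z", states, anns)

    def test_treemap_percentages(self):
        tree, states, anns = _annotated_states()
        records = {r["node_id"]: r for r in treemap_tables(states, anns)}
        leaf_a = records["A"]
        assert leaf_a["pct_multipurpose"] == pytest.approx(25.0)
        assert sum(leaf_a["single_purpose_pct"].values()) == pytest.approx(100.0)
        ab = tree.mrca(["A", "B"]).node_id
        assert records[ab]["pct_multipurpose"] == pytest.approx(50.0)
        assert records[tree.root.node_id]["pct_multipurpose"] == pytest.approx(0.0)

    def test_treemap_empty_node_flagged(self):
        tree = tree_from_newick("((A,B),C);")
        genomes = [make_genome(g, ["47473"]) for g in "AB"] + [make_genome("C", ["99999"])]
        states = dollo_reconstruct(tree, presence_from_genomes(genomes))
        anns = [ArchitectureAnnotation(parse_architecture("47473"), frozenset({"X"}))]
        records = {r["node_id"]: r for r in treemap_tables(states, anns)}
        assert records["C"]["empty"] is True
        assert records["C"]["pct_multipurpose"] is None
        assert records["A"]["empty"] is False


class TestTabularIO:
    def test_state_matrix_and_events_files(self, tmp_path):
        tree, states, _ = _annotated_states()
        sm = write_state_matrix(states, tmp_path / "states.tsv")
        lines = sm.read_text().strip().split("\n")
        assert len(lines) == 1 + len(tree.nodes)
        header = lines[0].split("\t")
        assert header[0] == "node_id"
        assert header[1:] == sorted(header[1:])
        ev = write_branch_events(branch_events(tree, states), tmp_path / "ev.tsv")
        rows = ev.read_text().strip().split("\n")[1:]
        assert rows == sorted(rows)

    def test_phyletic_matrix_reader(self, tmp_path):
        path = tmp_path / "phyletic.tsv"
        path.write_text(
            "architecture\tA\tB\tC\n47473\t1\t1\t0\n_gap_,56112\t0\t0\t1\n"
        )
        presence = read_phyletic_matrix(path)
        assert presence == {"47473": {"A", "B"}, "_gap_,56112": {"C"}}

    def test_phyletic_matrix_rejects_all_absent_row(self, tmp_path):
        path = tmp_path / "phyletic.tsv"
        path.write_text("architecture\tA\tB\n47473\t0\t0\n")
        with pytest.raises(ReconstructionError):
            read_phyletic_matrix(path)
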