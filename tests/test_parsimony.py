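"""Parsimony engine: Fitch lengths, MPR sets, DELTRAN and the apolist,
checked against exhaustive enumeration."""

import numpy as np
import pytest

from apoclass import (
    AminoAcidMatrix,
    GenePartition,
    RootedTree,
    apomorphy_list,
    consistency_index,
    fitch_down_pass,
    mpr_sets,
    reconstruct,
    site_changes,
)
from oracle import (
    enumerate_site,
    leaf_states_of,
    oracle_alphabet,
    oracle_deltran,
    random_binary_tree,
)


def one_site(tree_newick, outgroup, states):
    """Build a one-column matrix; states maps leaf -> symbol."""
    tree = RootedTree.from_newick(tree_newick, outgroup=outgroup)
    taxa = tree.leaf_labels
    matrix = AminoAcidMatrix(taxa, [states[t] for t in taxa])
    return tree, matrix


class TestFitchLength:
    @pytest.mark.parametrize(
        "states,expected",
        [
            ({"A": "I", "B": "I", "C": "V", "D": "V"}, 1),
            ({"A": "I", "B": "I", "C": "I", "D": "I"}, 0),
            ({"A": "I", "B": "X", "C": "V", "D": "V"}, 1),
            ({"A": "I", "B": "V", "C": "I", "D": "V"}, 2),
        ],
    )
    def test_quartet_lengths(self, states, expected):
        tree, matrix = one_site("((A,B),(C,D));", ["D"], states)
        _, length = fitch_down_pass(tree, matrix, 1)
        assert length == expected

    def test_missing_leaf_never_contributes(self):
        tree, matrix = one_site(
            "((A,B),(C,D));", ["D"], {"A": "I", "B": "I", "C": "V", "D": "V"}
        )
        base = reconstruct(tree, matrix, 1).length
        for taxon in "ABCD":
            states = {"A": "I", "B": "I", "C": "V", "D": "V"}
            states[taxon] = "X"
            _, m2 = one_site("((A,B),(C,D));", ["D"], states)
            assert reconstruct(tree, m2, 1).length <= base

    def test_site_out_of_range(self):
        tree, matrix = one_site(
            "((A,B),(C,D));", ["D"], {"A": "I", "B": "I", "C": "V", "D": "V"}
        )
        with pytest.raises(IndexError):
            reconstruct(tree, matrix, 2)


class TestMprSets:
    def test_forced_singleton(self):
        tree, matrix = one_site(
            "(((A,B),C),D);", ["D"],
            {"A": "G", "B": "A", "C": "A", "D": "A"},
        )
        sets = mpr_sets(tree, matrix, 1)
        cherry = tree.mrca(["A", "B"])
        assert sets[cherry.id] == frozenset({"A"})

    def test_invariant_site_singletons(self):
        tree, matrix = one_site(
            "((A,B),(C,D));", ["D"], {t: "L" for t in "ABCD"}
        )
        sets = mpr_sets(tree, matrix, 1)
        assert all(s == frozenset({"L"}) for s in sets.values())

    def test_matches_enumeration_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            nwk = random_binary_tree(rng, 6)
            labels = [chr(ord("a") + i) for i in range(6)]
            tree = RootedTree.from_newick(nwk, outgroup=[labels[-1]])
            pool = ["A", "C", "D", "X"]
            for _site in range(8):
                states = {lb: pool[rng.integers(0, 4)] for lb in labels}
                matrix = AminoAcidMatrix(labels, [states[lb] for lb in labels])
                ls = leaf_states_of(tree, matrix, 1)
                if len({s for s in ls.values() if s is not None}) < 2:
                    continue
                alpha = oracle_alphabet(ls)
                _, mpr, _, _, _ = enumerate_site(tree, ls, alpha)
                ours = mpr_sets(tree, matrix, 1)
                for node in tree.preorder():
                    if not node.is_leaf:
                        assert ours[node.id] == mpr[node.id]


class TestDeltran:
    def test_autapomorphy_on_terminal_edge(self):
        # the lone derived G arises on the branch to its leaf, not deeper
        tree, matrix = one_site(
            "(((A,B),C),Out);", ["Out"],
            {"A": "G", "B": "A", "C": "A", "Out": "A"},
        )
        rec = reconstruct(tree, matrix, 1)
        for node in tree.preorder():
            if not node.is_leaf:
                assert rec.final[node.id] == "A"
        changes = site_changes(tree, rec, matrix)
        assert len(changes) == 1
        assert tree.nodes[changes[0].child_node].label == "A"

    def test_invariant_site_zero_changes(self):
        tree, matrix = one_site(
            "((A,B),(C,D));", ["D"], {t: "P" for t in "ABCD"}
        )
        rec = reconstruct(tree, matrix, 1)
        assert rec.length == 0
        assert site_changes(tree, rec, matrix) == []

    def test_convergence_placed_on_terminal_edges(self):
        # derived R in two non-sister leaves: DELTRAN infers two tip-ward
        # origins rather than a deep gain plus a reversal
        tree, matrix = one_site(
            "((((A,B),C),D),Out);", ["Out"],
            {"A": "R", "B": "A", "C": "R", "D": "A", "Out": "A"},
        )
        rec = reconstruct(tree, matrix, 1)
        assert rec.length == 2
        changed = {
            tree.nodes[c.child_node].label for c in site_changes(tree, rec, matrix)
        }
        assert changed == {"A", "C"}
        for node in tree.preorder():
            if not node.is_leaf:
                assert rec.final[node.id] == "A"

    def test_inheritance_is_delayed(self):
        # definitional DELTRAN: a node keeps its parent's state whenever its
        # MPR set allows it
        rng = np.random.default_rng(2)
        for _ in range(30):
            nwk = random_binary_tree(rng, 7)
            labels = [chr(ord("a") + i) for i in range(7)]
            tree = RootedTree.from_newick(nwk, outgroup=[labels[-1]])
            pool = ["A", "C", "D", "X"]
            states = {lb: pool[rng.integers(0, 4)] for lb in labels}
            matrix = AminoAcidMatrix(labels, [states[lb] for lb in labels])
            if len(matrix.observed_states(1)) < 2:
                continue
            rec = reconstruct(tree, matrix, 1)
            for node in tree.preorder():
                if node.is_leaf or node.parent is None:
                    continue
                pstate = rec.final[node.parent.id]
                if pstate in rec.mpr[node.id]:
                    assert rec.final[node.id] == pstate

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 30:
            nl = int(rng.integers(4, 8))
            nwk = random_binary_tree(rng, nl)
            labels = [chr(ord("a") + i) for i in range(nl)]
            tree = RootedTree.from_newick(nwk, outgroup=[labels[-1]])
            pool = ["A", "C", "D", "X"]
            states = {lb: pool[rng.integers(0, 4)] for lb in labels}
            matrix = AminoAcidMatrix(labels, [states[lb] for lb in labels])
            ls = leaf_states_of(tree, matrix, 1)
            if len({s for s in ls.values() if s is not None}) < 2:
                continue
            checked += 1
            alpha = oracle_alphabet(ls)
            og_states = {ls[t] for t in tree.outgroup if ls[t] is not None}
            expected = oracle_deltran(tree, ls, alpha, og_states)
            rec = reconstruct(tree, matrix, 1)
            assert rec.final == expected


class TestSiteChanges:
    def test_stem_apomorphy_inherited_from_outgroup_state(self):
        # caterpillar: outgroup and basal leaf V, all others I -> a single
        # V->I change on the stem of the I-clade
        tree, matrix = one_site(
            "(((((A,B),C),D),E),Out);", ["Out"],
            {"A": "I", "B": "I", "C": "I", "D": "I", "E": "V", "Out": "V"},
        )
        rec = reconstruct(tree, matrix, 1)
        changes = site_changes(tree, rec, matrix)
        assert len(changes) == 1
        (c,) = changes
        assert (c.from_state, c.to_state) == ("V", "I")
        assert tree.leafset(tree.nodes[c.child_node]) == frozenset("ABCD")

    def test_outgroup_edges_excluded(self):
        tree, matrix = one_site(
            "((A,B),(C,D));", ["C", "D"],
            {"A": "I", "B": "I", "C": "V", "D": "L"},
        )
        rec = reconstruct(tree, matrix, 1)
        for c in site_changes(tree, rec, matrix):
            assert not (
                tree.leafset(tree.nodes[c.child_node]) & tree.outgroup
            )

    def test_conservation_sum_of_changes_equals_length(self):
        rng = np.random.default_rng(4)
        for _ in range(40):
            nl = int(rng.integers(4, 9))
            nwk = random_binary_tree(rng, nl)
            labels = [chr(ord("a") + i) for i in range(nl)]
            tree = RootedTree.from_newick(nwk, outgroup=[labels[-1]])
            pool = ["A", "C", "D", "G", "X"]
            states = {lb: pool[rng.integers(0, 5)] for lb in labels}
            matrix = AminoAcidMatrix(labels, [states[lb] for lb in labels])
            rec = reconstruct(tree, matrix, 1)
            n_diff = 0
            for node in tree.preorder():
                if node.parent is None:
                    continue
                if node.is_leaf and states[node.label] == "X":
                    continue
                if rec.final[node.id] != rec.final[node.parent.id]:
                    n_diff += 1
            assert n_diff == rec.length


class TestConsistencyIndex:
    def test_values(self):
        tree, matrix = one_site(
            "((((A,B),C),D),Out);", ["Out"],
            {"A": "R", "B": "A", "C": "R", "D": "A", "Out": "A"},
        )
        # convergent R: k=2 over 2 changes
        assert consistency_index(matrix, 1, reconstruct(tree, matrix, 1).length) == 0.5
        tree2, m2 = one_site(
            "((A,B),(C,D));", ["D"], {"A": "I", "B": "I", "C": "V", "D": "V"}
        )
        assert consistency_index(m2, 1, 1) == 1.0
        # three states over two changes is also homoplasy-free
        tree3, m3 = one_site(
            "((A,B),(C,D));", ["D"], {"A": "I", "B": "I", "C": "V", "D": "L"}
        )
        assert consistency_index(m3, 1, reconstruct(tree3, m3, 1).length) == 1.0

    def test_invariant_undefined(self):
        _, matrix = one_site(
            "((A,B),(C,D));", ["D"], {t: "K" for t in "ABCD"}
        )
        with pytest.raises(ValueError):
            consistency_index(matrix, 1, 0)


class TestApomorphyList:
    def test_planted_apomorphies_recovered(self, clean_sim):
        apl = apomorphy_list(clean_sim.tree, clean_sim.matrix, clean_sim.partition)
        planted = {
            (p.clade_node, p.site, p.from_state, p.to_state)
            for p in clean_sim.truth.planted
        }
        mined = {(c.child_node, c.site, c.from_state, c.to_state) for c in apl}
        assert mined == planted
        assert all(c.ci == 1.0 for c in apl)

    def test_invariant_matrix_empty(self):
        tree = RootedTree.from_newick("((A,B),(C,D));", outgroup=["D"])
        matrix = AminoAcidMatrix(["A", "B", "C", "D"], ["KKK"] * 4)
        assert apomorphy_list(tree, matrix) == []

    def test_deterministic_order(self, clean_sim):
        apl = apomorphy_list(clean_sim.tree, clean_sim.matrix, clean_sim.partition)
        assert [c.site for c in apl] == sorted(c.site for c in apl)

    def test_entries_match_oracle_changes(self):
        # every apolist entry corresponds to an edge difference of the
        # enumeration-oracle DELTRAN labeling
        rng = np.random.default_rng(5)
        labels = [chr(ord("a") + i) for i in range(6)]
        nwk = random_binary_tree(rng, 6)
        tree = RootedTree.from_newick(nwk, outgroup=[labels[-1]])
        pool = ["A", "C", "D", "X"]
        rows = {
            lb: "".join(pool[rng.integers(0, 4)] for _ in range(40))
            for lb in labels
        }
        matrix = AminoAcidMatrix(labels, [rows[lb] for lb in labels])
        apl = apomorphy_list(tree, matrix)
        by_site = {}
        for c in apl:
            by_site.setdefault(c.site, []).append(c)
        for site in range(1, 41):
            ls = leaf_states_of(tree, matrix, site)
            if len({s for s in ls.values() if s is not None}) < 2:
                assert site not in by_site
                continue
            alpha = oracle_alphabet(ls)
            og_states = {ls[t] for t in tree.outgroup if ls[t] is not None}
            finals = oracle_deltran(tree, ls, alpha, og_states)
            expected = set()
            for node in tree.preorder():
                if node.parent is None or not tree.is_ingroup_node(node):
                    continue
                if node.is_leaf and ls[node.label] is None:
                    continue
                if finals[node.id] != finals[node.parent.id]:
                    expected.add(
                        (node.id, finals[node.parent.id], finals[node.id])
                    )
            got = {
                (c.child_node, c.from_state, c.to_state)
                for c in by_site.get(site, [])
            }
            assert got == expected
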