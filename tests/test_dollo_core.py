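"""Tree handling and the Dollo loss-counting engine."""

import numpy as np
import pytest

from dolloloss.bruteforce import dollo_score_bruteforce
from dolloloss.dollo_core import (
    ROOT_BRANCH,
    Phylo,
    collapse_branch,
    dollo_fit,
    read_newick,
    tree_score,
    write_newick,
)
from dolloloss.evaluation import random_tree
from dolloloss.toga_io import PresenceMatrix

from conftest import random_matrix


class TestNewick:
    def test_parse_counts_nodes(self):
        t = read_newick("((A,B),(C,D));")
        assert sorted(t.leaf_labels) == ["A", "B", "C", "D"]
        assert len(t.postorder()) == 7

    def test_polytomy_preserved(self):
        t = read_newick("((A,B),(C,D),E);")
        assert len(t.root.children) == 3

    def test_roundtrip_17_leaf_fixture(self):
        from dolloloss.synthetic_data import atlantogenata_tree

        t = atlantogenata_tree()
        assert t.n_leaves() == 17
        text = write_newick(t)
        again = read_newick(text)
        assert write_newick(again) == text
        assert again.topology_key() == t.topology_key()
        assert again.branch_lengths() == t.branch_lengths()

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="[Dd]uplicate"):
            read_newick("((A,B),(A,C));")

    def test_unbalanced_rejected(self):
        with pytest.raises(ValueError):
            read_newick("((A,B),(C,D);")


class TestDolloFit:
    @pytest.mark.parametrize(
        "char,expected_losses,expected_branches",
        [
            ({"A": 1, "B": 0, "C": 0, "D": 0}, 2, {"B", "C|D"}),
            ({"A": 1, "B": 1, "C": 1, "D": 1}, 0, set()),
            ({"A": 1, "B": "?", "C": 0, "D": 0}, 1, {"C|D"}),
            ({"A": 0, "B": 0, "C": 0, "D": 0}, 2, {"A|B", "C|D"}),
            ({"A": 1, "B": 0, "C": "?", "D": "?"}, 1, {"B"}),
        ],
    )
    def test_quartet_cases(self, quartet, char, expected_losses, expected_branches):
        fit = dollo_fit(quartet, char, root_present=True)
        assert fit.losses == expected_losses
        assert set(fit.loss_branches) == expected_branches
        assert fit.gain_branch == ROOT_BRANCH
        assert fit.losses == dollo_score_bruteforce(quartet, char, root_present=True)

    def test_free_gain_at_mrca(self, quartet):
        fit = dollo_fit(quartet, {"A": 1, "B": 1, "C": 0, "D": 0}, root_present=False)
        assert fit.losses == 0
        assert fit.gain_branch == "A|B"
        none = dollo_fit(quartet, {"A": 0, "B": 0, "C": 0, "D": 0}, root_present=False)
        assert none.losses == 0 and none.gain_branch is None

    def test_unknown_leaf_rejected(self, quartet):
        with pytest.raises(ValueError, match="not in tree"):
            dollo_fit(quartet, {"A": 1, "Z": 0})

    def test_oracle_equivalence_random(self, rng):
        labels = list("ABCDEFG")
        for _ in range(120):
            n = int(rng.integers(4, 8))
            tree = random_tree(labels[:n], rng)
            char = {
                lab: ("?" if v == 3 else min(int(v), 1))
                for lab, v in zip(labels[:n], rng.integers(0, 4, size=n))
            }
            root_present = bool(rng.integers(0, 2))
            fit = dollo_fit(tree, char, root_present=root_present)
            assert fit.losses == dollo_score_bruteforce(
                tree, char, root_present=root_present
            )

    def test_loss_branches_non_nested(self, rng):
        labels = list("ABCDEF")
        for _ in range(50):
            tree = random_tree(labels, rng)
            char = {lab: int(v) for lab, v in zip(labels, rng.integers(0, 2, 6))}
            fit = dollo_fit(tree, char)
            clades = [tree.clade(b) for b in fit.loss_branches]
            for i, a in enumerate(clades):
                for b in clades[i + 1 :]:
                    assert not (a <= b or b <= a)


class TestTreeScore:
    def test_invariant_characters_are_free(self, quartet):
        m = PresenceMatrix(list("ABCD"), ["g1", "g2", "g3"], np.ones((4, 3)))
        assert tree_score(quartet, m) == 0

    def test_column_duplication_doubles_score(self, quartet, rng):
        m = random_matrix(rng, list("ABCD"), 10)
        doubled = PresenceMatrix(
            m.species, m.genes + [g + "b" for g in m.genes],
            np.hstack([m.states, m.states]),
        )
        assert tree_score(quartet, doubled) == 2 * tree_score(quartet, m)

    def test_total_is_sum_of_fits(self, quartet, rng):
        m = random_matrix(rng, list("ABCD"), 25)
        per_char = sum(
            dollo_fit(quartet, m.character(g)).losses for g in m.genes
        )
        assert tree_score(quartet, m) == per_char

    def test_species_mismatch_lists_difference(self, quartet):
        m = PresenceMatrix(["A", "B", "C", "E"], ["g"], np.ones((4, 1)))
        with pytest.raises(ValueError, match="E"):
            tree_score(quartet, m)


class TestCollapse:
    def test_collapse_definition(self, quartet):
        star_half = collapse_branch(quartet, "A|B")
        assert star_half.topology_key() == "((C,D),A,B);"

    def test_star_tree_scores_each_zero_leaf(self, quartet):
        star = collapse_branch(collapse_branch(quartet, "A|B"), "C|D")
        fit = dollo_fit(star, {"A": 1, "B": 0, "C": 0, "D": 0})
        assert fit.losses == 3
        assert fit.losses == dollo_score_bruteforce(
            star, {"A": 1, "B": 0, "C": 0, "D": 0}
        )

    def test_leaf_edge_rejected(self, quartet):
        with pytest.raises(ValueError, match="terminal"):
            collapse_branch(quartet, "A")

    def test_collapse_never_decreases_score(self, rng):
        labels = list("ABCDEF")
        for _ in range(30):
            tree = random_tree(labels, rng)
            char = {lab: int(v) for lab, v in zip(labels, rng.integers(0, 2, 6))}
            base = dollo_fit(tree, char).losses
            for bid in tree.internal_branch_ids():
                collapsed = collapse_branch(tree, bid)
                assert dollo_fit(collapsed, char).losses >= base


class TestRestrictionBound:
    def test_stem_score_monotone_under_leaf_removal(self, rng):
        from dolloloss.dollo_core import per_gene_losses

        labels = list("ABCDEFG")
        for _ in range(30):
            tree = random_tree(labels, rng)
            states = rng.integers(0, 2, size=(7, 15)).astype(np.int8)
            full = per_gene_losses(tree, states, labels, allzero_policy="stem")
            victim = labels[int(rng.integers(7))]
            pruned = tree.prune_leaf(victim)
            keep = [i for i, lab in enumerate(labels) if lab != victim]
            sub = per_gene_losses(
                pruned, states[keep], [labels[i] for i in keep],
                allzero_policy="stem",
            )
            assert np.all(sub <= full)
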