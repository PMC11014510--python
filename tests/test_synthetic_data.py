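"""The gene-loss simulator and its ground truth."""

import math

import numpy as np
import pytest

from dolloloss.dollo_core import read_newick
from dolloloss.synthetic_data import (
    CLADE_FIXTURE_CLADES,
    LossSimConfig,
    atlantogenata_species_tree,
    atlantogenata_tree,
    clade_fixture,
    simulate_enriched_sets,
    simulate_losses,
    write_fixture_files,
)
from dolloloss.toga_io import assemble_matrix, code_presence, parse_toga_summary


@pytest.fixture(scope="module")
def fixture_tree():
    return atlantogenata_tree()


class TestFixtureTree:
    def test_seventeen_species_and_named_clades(self, fixture_tree):
        assert fixture_tree.n_leaves() == 17
        for clade in ("Afrotheria", "Xenarthra", "Paenungulata",
                      "Afroinsectiphilia", "Cingulata", "Pilosa"):
            assert fixture_tree.has_branch(clade)
        assert fixture_tree.clade("Paenungulata") >= {
            "african_elephant", "rock_hyrax", "west_indian_manatee",
        }
        assert len(fixture_tree.clade("Afrotheria")) == 12

    def test_all_branches_have_lengths(self, fixture_tree):
        lengths = fixture_tree.branch_lengths()
        assert len(lengths) == len(fixture_tree.branch_ids())
        assert all(v > 0 for v in lengths.values())

    def test_polytomy_variant_collapses_paenungulate_order(self):
        tree = atlantogenata_species_tree()
        node = tree.node("Paenungulata")
        assert len(node.children) == 3
        assert not tree.has_branch("Tethytheria")


class TestSimulator:
    def test_zero_rate_means_no_losses(self, fixture_tree):
        cfg = LossSimConfig(tree=fixture_tree, n_genes=50, base_rate=0.0, seed=1)
        truth = simulate_losses(cfg)
        assert truth.matrix.states.all()
        assert sum(truth.branch_counts.values()) == 0

    def test_single_edge_survival_probability(self):
        # one branch of length t with rate λ such that λt = ln 2: half lost
        tree = read_newick("(tip:1.0,other:0.0);")
        cfg = LossSimConfig(tree=tree, n_genes=10_000, base_rate=math.log(2), seed=2)
        truth = simulate_losses(cfg)
        i = truth.matrix.species.index("tip")
        frac = 1.0 - truth.matrix.states[i].mean()
        se = math.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac - 0.5) < 3 * se

    def test_zero_multiplier_suppresses_branch(self, fixture_tree):
        cfg = LossSimConfig(
            tree=fixture_tree, n_genes=300, base_rate=5e-3,
            branch_multipliers={"Afrotheria": 0.0}, seed=3,
        )
        truth = simulate_losses(cfg)
        assert truth.branch_counts["Afrotheria"] == 0
        assert all("Afrotheria" not in b for b in truth.gene_loss_branches)

    def test_irreversibility_matrix_consistent_with_truth(self, fixture_tree):
        cfg = LossSimConfig(tree=fixture_tree, n_genes=200, base_rate=2e-3, seed=4)
        truth = simulate_losses(cfg)
        for gene_i, branches in enumerate(truth.gene_loss_branches):
            below = set()
            for bid in branches:
                clade = fixture_tree.clade(bid)
                assert not (below & clade)  # loss branches are disjoint subtrees
                below |= clade
            for sp_i, sp in enumerate(truth.matrix.species):
                expected = 0 if sp in below else 1
                assert truth.matrix.states[sp_i, gene_i] == expected

    def test_leafwise_loss_fraction_matches_closed_form(self, fixture_tree):
        cfg = LossSimConfig(tree=fixture_tree, n_genes=10_000, base_rate=1e-3, seed=5)
        truth = simulate_losses(cfg)
        lengths = fixture_tree.branch_lengths()
        for leaf in list(fixture_tree.leaves())[:5]:
            path = 0.0
            node = leaf
            while node is not fixture_tree.root:
                path += lengths[fixture_tree.branch_id(node)]
                node = node.parent
            expect = 1.0 - math.exp(-cfg.base_rate * path)
            i = truth.matrix.species.index(leaf.label)
            frac = 1.0 - truth.matrix.states[i].mean()
            se = math.sqrt(expect * (1 - expect) / cfg.n_genes)
            assert abs(frac - expect) < 4 * se

    def test_determinism(self, fixture_tree):
        cfg = LossSimConfig(tree=fixture_tree, n_genes=100, base_rate=2e-3, seed=6)
        a, b = simulate_losses(cfg), simulate_losses(cfg)
        assert a.matrix == b.matrix
        assert a.gene_loss_branches == b.gene_loss_branches

    def test_missing_length_rejected(self):
        tree = read_newick("((A,B):1,(C:1,D:1):1);")
        with pytest.raises(ValueError, match="no length"):
            simulate_losses(LossSimConfig(tree=tree, n_genes=5, base_rate=0.1))


@pytest.fixture(scope="module")
def truth():
    from dolloloss.synthetic_data import burst_fixture_config

    return simulate_losses(burst_fixture_config(seed=7))


class TestEnrichedSets:
    def test_designation_bookkeeping(self, truth):
        coll, designated = simulate_enriched_sets(
            truth, n_sets=10, n_enriched=2, focal_branch="Afrotheria",
            boost=4.0, seed=1,
        )
        assert len(designated) == 2
        assert set(designated) <= set(coll.terms())

    def test_null_mode_has_no_designated_sets(self, truth):
        coll, designated = simulate_enriched_sets(
            truth, n_sets=8, n_enriched=0, focal_branch="Afrotheria",
            boost=4.0, seed=2,
        )
        assert designated == []

    def test_designated_sets_reach_target_fold(self, truth):
        coll, designated = simulate_enriched_sets(
            truth, n_sets=10, set_size_range=(30, 50), n_enriched=2,
            focal_branch="Afrotheria", boost=4.0, seed=3,
        )
        focal = truth.focal_lost_genes("Afrotheria")
        background_frac = len(focal) / len(truth.gene_names)
        for term in designated:
            members = coll.members(term)
            frac = sum(g in focal for g in members) / len(members)
            assert frac >= 4.0 * background_frac * 0.95  # ceil() can only help

    def test_sets_partition_disjointly(self, truth):
        coll, _ = simulate_enriched_sets(
            truth, n_sets=12, n_enriched=2, focal_branch="Afrotheria",
            boost=3.0, seed=4,
        )
        seen = set()
        for term in coll.terms():
            members = set(coll.members(term))
            assert not (members & seen)
            seen |= members


class TestFixtureFiles:
    def test_roundtrip_through_loss_summary_parser(self, tmp_path, fixture_tree):
        cfg = LossSimConfig(tree=fixture_tree, n_genes=60, base_rate=2e-3, seed=8)
        truth = simulate_losses(cfg)
        write_fixture_files(truth, tmp_path)
        files = sorted(tmp_path.glob("loss_summ.*.tsv"))
        assert len(files) == 17
        per_species = {
            f.name[len("loss_summ."):-len(".tsv")]: code_presence(
                parse_toga_summary(f)
            )
            for f in files
        }
        rebuilt = assemble_matrix(per_species)
        # same content; species order may differ (files are sorted)
        assert rebuilt.genes == truth.matrix.genes
        for sp in truth.matrix.species:
            i, j = rebuilt.species.index(sp), truth.matrix.species.index(sp)
            assert (rebuilt.states[i] == truth.matrix.states[j]).all()


class TestCladeFixture:
    def test_clades_cover_all_species_disjointly(self, fixture_tree):
        union = set()
        for clade in CLADE_FIXTURE_CLADES:
            members = fixture_tree.clade(clade)
            assert not (union & members)
            union |= members
        assert union == set(fixture_tree.leaf_labels)

    def test_stem_blocks_dominate_structure(self):
        truth, labels = clade_fixture(seed=9, n_genes=800)
        # each clade stem should carry a large block of shared losses
        for clade in CLADE_FIXTURE_CLADES:
            assert truth.branch_counts[clade] > 0.2 * 800
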