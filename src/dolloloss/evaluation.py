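"""End-to-end validation experiments.

Each routine here runs one of the package's property-based checks from
scratch — simulate (or construct) inputs, run the pipeline, measure the
result — and returns plain numbers.  They are shared by the test suite
and by ``scripts/acceptance.py`` so both always report the same
quantities computed the same way.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence` spawning, so every routine is
reproducible and the experiments are mutually independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from .ancestral_losses import (
    branch_regression,
    foreground_from_reconstruction,
    reconstruct_losses,
)
from .bruteforce import (
    all_rooted_binary_trees,
    dollo_score_bruteforce,
    hypergeom_sf_exact,
)
from .cluster_explore import fuzzy_cluster, pairwise_distances, reduce_and_partition
from .dollo_core import Node, Phylo, dollo_fit, read_newick, tree_score
from .enrichment import ora
from .synthetic_data import (
    LossSimConfig,
    burst_fixture_config,
    clade_fixture,
    clade_marker_matrix,
    simulate_enriched_sets,
    simulate_losses,
)
from .toga_io import PresenceMatrix
from .topology_tests import branch_sh_scan, templeton_p
from .tree_search import bootstrap_consensus, branch_and_bound

__all__ = [
    "random_tree",
    "dollo_oracle_agreement",
    "exact_search_agreement",
    "reconstruction_conservation",
    "burst_detection_rate",
    "topology_recovery",
    "bootstrap_support_floor",
    "zero_support_branch_check",
    "templeton_null_rejection",
    "hypergeom_max_rel_error",
    "ora_null_rejection",
    "enrichment_recovery",
    "clustering_recovery",
]


def _child_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31 - 1))


def random_tree(labels, rng: np.random.Generator) -> Phylo:
    """Uniform-ish random rooted binary tree by random stepwise addition."""
    labels = list(labels)
    root = Node(None, None, [Node(labels[0]), Node(labels[1])])
    for label in labels[2:]:
        nodes = []
        stack = [root]
        while stack:
            node = stack.pop()
            nodes.append(node)
            stack.extend(node.children)
        target = nodes[int(rng.integers(len(nodes)))]
        parent = target.parent  # capture before the joint re-parents target
        joint = Node(None, None, [target, Node(label)])
        if parent is None:
            root = joint
        else:
            parent.children[parent.children.index(target)] = joint
            joint.parent = parent
    # deep copy to detach bookkeeping
    def copy(n: Node) -> Node:
        new = Node(n.label, n.length)
        for c in n.children:
            new.add_child(copy(c))
        return new

    return Phylo(copy(root))


# ----------------------------------------------------------- dollo vs oracle


def dollo_oracle_agreement(seed: int = 0, n_chars: int = 200) -> dict:
    """Fraction of random (tree, character) instances on <=7 leaves where
    the Dollo engine equals exhaustive single-gain/any-loss enumeration."""
    rng = np.random.default_rng(_child_seed(seed, 1))
    labels = list("ABCDEFG")
    agree = 0
    for _ in range(n_chars):
        n_leaves = int(rng.integers(4, 8))
        tree = random_tree(labels[:n_leaves], rng)
        char = {}
        for lab in labels[:n_leaves]:
            v = int(rng.integers(0, 4))
            char[lab] = "?" if v == 3 else min(v, 1)
        root_present = bool(rng.integers(0, 2))
        fit = dollo_fit(tree, char, root_present=root_present)
        oracle = dollo_score_bruteforce(tree, char, root_present=root_present)
        agree += fit.losses == oracle
    return {"agreement": agree / n_chars, "n": n_chars}


def exact_search_agreement(
    seed: int = 0, n_instances: int = 50, n_taxa: int = 6, n_genes: int = 20
) -> dict:
    """Fraction of random matrices where branch-and-bound matches the
    minimum over full topology enumeration."""
    rng = np.random.default_rng(_child_seed(seed, 2))
    labels = [chr(ord("A") + i) for i in range(n_taxa)]
    topologies = list(all_rooted_binary_trees(labels))
    agree = 0
    for _ in range(n_instances):
        states = rng.integers(0, 2, size=(n_taxa, n_genes)).astype(np.int8)
        matrix = PresenceMatrix(labels, [f"g{j}" for j in range(n_genes)], states)
        result = branch_and_bound(matrix)
        best_enum = min(tree_score(t, matrix) for t in topologies)
        agree += result.best_score == best_enum
    return {"agreement": agree / n_instances, "n": n_instances}


# ----------------------------------------------------------- reconstruction


def reconstruction_conservation(seed: int = 0, n_fixtures: int = 10) -> dict:
    """Max |Σ per-branch losses − tree_score| over simulated fixtures."""
    worst = 0
    for i in range(n_fixtures):
        cfg = burst_fixture_config(seed=_child_seed(seed, 100 + i), n_genes=500)
        truth = simulate_losses(cfg)
        rec = reconstruct_losses(cfg.tree, truth.matrix)
        worst = max(worst, abs(rec.total_losses - tree_score(cfg.tree, truth.matrix)))
    return {"max_abs_diff": worst, "n": n_fixtures}


def burst_detection_rate(seed: int = 0, n_reps: int = 100) -> dict:
    """Fraction of burst-fixture simulations in which the regression flags
    the 5× burst stem branch as a loss-rate outlier."""
    hits = 0
    for i in range(n_reps):
        cfg = burst_fixture_config(seed=_child_seed(seed, 200 + i))
        truth = simulate_losses(cfg)
        rec = reconstruct_losses(cfg.tree, truth.matrix)
        reg = branch_regression(rec)
        hits += "Afrotheria" in reg.outlier_branches
    return {"detection_rate": hits / n_reps, "n": n_reps}


# ------------------------------------------------------------ tree recovery

RECOVERY_TREE = "((A:10,B:10):10,((C:10,D:10):10,(E:20,(F:10,G:10):10):10):10);"
RECOVERY_RATE = 0.005
RECOVERY_GENES = 400


def topology_recovery(seed: int = 0, n_sims: int = 20) -> dict:
    """Exact-search recovery of a 7-leaf generating topology.

    Simulations qualify when every internal branch of the generating tree
    carries at least 5 exclusive losses (genes lost on that branch and
    nowhere else); recovery means the generating topology is the unique
    optimum."""
    gen = read_newick(RECOVERY_TREE)
    internal = gen.internal_branch_ids()
    gen_key = gen.topology_key()
    qualified = recovered = 0
    for i in range(n_sims):
        cfg = LossSimConfig(
            tree=gen,
            n_genes=RECOVERY_GENES,
            base_rate=RECOVERY_RATE,
            seed=_child_seed(seed, 300 + i),
        )
        truth = simulate_losses(cfg)
        exclusive = truth.exclusive_loss_counts()
        if any(exclusive[b] < 5 for b in internal):
            continue
        qualified += 1
        result = branch_and_bound(truth.matrix)
        if len(result.best_trees) == 1 and result.headline_tree.topology_key() == gen_key:
            recovered += 1
    rate = recovered / qualified if qualified else float("nan")
    return {"recovery_rate": rate, "n_qualified": qualified, "n": n_sims}


def bootstrap_support_floor(seed: int = 0, n_reps: int = 100) -> dict:
    """Minimum bootstrap support over the true internal branches on the
    strong-signal fixture (20 exclusive loss characters per branch, plus
    terminal noise)."""
    gen = read_newick("((A,B),((C,D),(E,(F,G))));")
    matrix = clade_marker_matrix(gen, per_branch=20, terminal_per_leaf=3,
                                 n_invariant=10)
    cons = bootstrap_consensus(matrix, n_reps=n_reps, seed=_child_seed(seed, 4))
    true_clades = {gen.clade(b) for b in gen.internal_branch_ids()}
    cons_clades = {
        cons.tree.clade(b): s for b, s in cons.supports.items()
    }
    floor = min(cons_clades.get(c, 0.0) for c in true_clades)
    return {"min_support": floor, "n_reps": n_reps,
            "n_true_branches": len(true_clades)}


# ------------------------------------------------------------ topology tests


def zero_support_branch_check(seed: int = 0) -> dict:
    """A branch no character supports must give delta 0 and p 1."""
    tree = read_newick("((A,B),(C,D));")
    matrix = clade_marker_matrix(tree, per_branch=0, branches=[],
                                 terminal_per_leaf=3, n_invariant=5)
    results = branch_sh_scan(tree, matrix, n_resamples=2000,
                             seed=_child_seed(seed, 5))
    worst_delta = max(r.delta for r in results)
    worst_p = min(min(r.p_templeton, r.p_rell) for r in results)
    return {"max_delta": worst_delta, "min_p": worst_p,
            "n_branches": len(results)}


def templeton_null_rejection(
    seed: int = 0, n_pairs: int = 2000, n_genes: int = 200
) -> dict:
    """Rejection rate of the Templeton test at alpha = 0.05 on exchangeable
    null score-difference profiles (random symmetric ± differences)."""
    rng = np.random.default_rng(_child_seed(seed, 6))
    rejected = 0
    for _ in range(n_pairs):
        mags = rng.choice([0, 1, 2, 3], size=n_genes, p=[0.3, 0.4, 0.2, 0.1])
        signs = rng.choice([-1, 1], size=n_genes)
        p = templeton_p(mags * signs)
        rejected += p < 0.05
    return {"rejection_rate": rejected / n_pairs, "n": n_pairs}


# -------------------------------------------------------------------- ORA


def hypergeom_max_rel_error(seed: int = 0, n_evals: int = 300) -> dict:
    """Worst relative error of the tail p against exact rational
    arithmetic, N <= 200."""
    rng = np.random.default_rng(_child_seed(seed, 7))
    worst = 0.0
    for _ in range(n_evals):
        N = int(rng.integers(5, 201))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        k = int(rng.integers(0, min(K, n) + 1))
        approx = float(stats.hypergeom.sf(k - 1, N, K, n))
        exact = float(hypergeom_sf_exact(k, N, K, n))
        rel = abs(approx - exact) / exact if exact else abs(approx - exact)
        worst = max(worst, rel)
    return {"max_rel_error": worst, "n": n_evals}


def ora_null_rejection(seed: int = 0, n_draws: int = 2000) -> dict:
    """False-positive rate at p < 0.05 for random foregrounds of the true size.

    Uses the enrichment fixture's own conditions: the background is the
    simulated gene universe, the foreground size is the size the
    reconstruction's internal-branch foreground actually has there, and
    the tested sets are the fixture's annotation collection (restricted to
    the usual size window)."""
    cfg = burst_fixture_config(seed=_child_seed(seed, 8))
    truth = simulate_losses(cfg)
    rec = reconstruct_losses(cfg.tree, truth.matrix)
    n_fg = len(foreground_from_reconstruction(rec, internal_only=True))
    collection, _ = simulate_enriched_sets(
        truth, n_sets=40, set_size_range=(30, 60), n_enriched=0,
        focal_branch="Afrotheria", boost=8.0, seed=_child_seed(seed, 14),
    )
    gene_index = {g: i for i, g in enumerate(truth.gene_names)}
    n_bg = len(truth.gene_names)
    sizes = []
    member_rows = []
    for term in collection.terms():
        members = collection.members(term)
        if not 10 <= len(members) <= 200:
            continue
        row = np.zeros(n_bg, dtype=bool)
        row[[gene_index[g] for g in members]] = True
        member_rows.append(row)
        sizes.append(len(members))
    membership = np.stack(member_rows)
    rng = np.random.default_rng(_child_seed(seed, 15))
    rejected = 0
    chunk = 500
    done = 0
    while done < n_draws:
        b = min(chunk, n_draws - done)
        X = np.zeros((b, n_bg), dtype=bool)
        for i in range(b):
            X[i, rng.choice(n_bg, size=n_fg, replace=False)] = True
        counts = X.astype(np.int32) @ membership.T.astype(np.int32)  # b × sets
        for j, K in enumerate(sizes):
            p = stats.hypergeom.sf(counts[:, j] - 1, n_bg, int(K), n_fg)
            rejected += int((p < 0.05).sum())
        done += b
    return {"rejection_rate": rejected / (n_draws * len(sizes)),
            "n_draws": n_draws, "n_sets": len(sizes), "n_fg": n_fg}


def enrichment_recovery(seed: int = 0) -> dict:
    """Full-pipeline enrichment fixture: simulate a burst, reconstruct, take
    the internal-branch foreground, test a collection whose designated sets
    over-sample burst-branch losses; measure designated recovery at
    q <= 0.10 and the non-designated discovery rate."""
    cfg = burst_fixture_config(seed=_child_seed(seed, 9))
    truth = simulate_losses(cfg)
    rec = reconstruct_losses(cfg.tree, truth.matrix)
    foreground = foreground_from_reconstruction(rec, internal_only=True)
    collection, designated = simulate_enriched_sets(
        truth,
        n_sets=40,
        set_size_range=(30, 60),
        n_enriched=3,
        focal_branch="Afrotheria",
        boost=8.0,
        seed=_child_seed(seed, 10),
    )
    rows = ora(foreground, truth.gene_names, collection, min_size=10, max_size=200)
    hits = {r.term for r in rows if r.q <= 0.10}
    designated = set(designated)
    tested = {r.term for r in rows}
    recovered = len(hits & designated) / len(designated)
    others = tested - designated
    false_rate = len(hits & others) / len(others) if others else 0.0
    return {
        "designated_recovery": recovered,
        "nondesignated_rate": false_rate,
        "n_designated": len(designated),
        "n_sets_tested": len(tested),
    }


# -------------------------------------------------------------- clustering


def clustering_recovery(seed: int = 0, K: int = 4) -> dict:
    """ARI of fuzzy-clustering and MDS+k-means partitions against the true
    clades on the clade-structured loss fixture, at the true K."""
    truth, labels = clade_fixture(seed=_child_seed(seed, 11))
    D = pairwise_distances(truth.matrix, "manhattan")
    true_vec = [labels[s] for s in D.labels]
    fm = fuzzy_cluster(D, K=K, m=1.2, seed=_child_seed(seed, 12))
    hard = fm.hard_labels()
    ari_fcm = adjusted_rand_score(true_vec, [hard[s] for s in D.labels])
    _, part = reduce_and_partition(D, dims=4, K=K, seed=_child_seed(seed, 13))
    ari_km = adjusted_rand_score(true_vec, [part[s] for s in D.labels])
    return {"fcm_ari": float(ari_fcm), "kmeans_ari": float(ari_km),
            "n_species": len(D.labels)}
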