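"""Most-parsimonious tree inference under the Dollo criterion.

Exact branch-and-bound enumerates rooted binary topologies by stepwise
taxon addition.  Pruning relies on the restriction bound: the Dollo score
of a character on a leaf-induced subtree never exceeds its score on the
full tree, provided characters whose observed leaves are all 0 are charged
a single loss on a virtual root edge (the "stem" convention).  Partial
trees are therefore scored with that convention; on binary trees it
differs from the public per-root-child convention by exactly one loss per
all-0 column, a topology-independent constant, so the optimum is the same
and final scores are reported with :func:`dolloloss.dollo_core.tree_score`.

Beyond the exact range, a heuristic search combines random-addition-order
stepwise trees with nearest-neighbour-interchange (NNI) hill climbing.

Branch support comes from bootstrap resampling of gene columns with a
majority-rule consensus of the per-replicate best trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .dollo_core import Node, Phylo, per_gene_losses, tree_score
from .toga_io import PresenceMatrix

__all__ = [
    "SearchResult",
    "ConsensusTree",
    "branch_and_bound",
    "heuristic_search",
    "bootstrap_consensus",
]


@dataclass
class SearchResult:
    best_score: int
    best_trees: list[Phylo]  # all co-optimal, canonical-sorted
    evaluated: int  # partial/complete trees scored
    mode: str  # "exact" | "heuristic"

    @property
    def headline_tree(self) -> Phylo:
        """First co-optimal tree by canonical topology sort."""
        return self.best_trees[0]


@dataclass
class ConsensusTree:
    tree: Phylo
    supports: dict[str, float]  # branch id -> percent of replicates

    def newick_with_support(self) -> str:
        new = self.tree.copy()
        for old_node, new_node in zip(self.tree.postorder(), new.postorder()):
            if old_node is not self.tree.root and not old_node.is_leaf():
                bid = self.tree.branch_id(old_node)
                new_node.label = format(self.supports.get(bid, 0.0), "g")
        return Phylo(new.root).newick(lengths=False)


# ------------------------------------------------------------ scoring core


def _stem_score(root: Node, states: np.ndarray, row: dict[str, int]) -> int:
    """Total Dollo losses (stem convention) of the leaves present in *root*.

    Operates directly on a Node structure so search trees need no Phylo
    indexing; leaves absent from the tree simply do not constrain anything
    (taxon restriction).
    """
    total = 0

    def visit(node: Node):
        nonlocal total
        if node.is_leaf():
            return states[row[node.label]] == 1
        has1 = None
        child_flags = []
        for child in node.children:
            flag = visit(child)
            child_flags.append(flag)
            has1 = flag if has1 is None else (has1 | flag)
        for flag in child_flags:
            total += int((~flag & has1).sum())
        return has1

    root_has1 = visit(root)
    total += int((~root_has1).sum())  # all-0 columns: one loss on the root stem
    return total


def _prepare(matrix: PresenceMatrix):
    states = np.asarray(matrix.states, dtype=np.int8)
    row = {s: i for i, s in enumerate(matrix.species)}
    return states, row


def _n_allzero_columns(matrix: PresenceMatrix) -> int:
    return int((matrix.states.sum(axis=0) == 0).sum())


# ------------------------------------------------------- stepwise machinery


def _two_taxon_tree(a: str, b: str) -> Node:
    return Node(None, None, [Node(a), Node(b)])


def _all_nodes(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        out.append(node)
        stack.extend(node.children)
    return out


def _insert_above(root: Node, target: Node, leaf_label: str):
    """Attach a new leaf above *target*; returns (new_root, joint_node)."""
    joint = Node(None, None, [])
    parent = target.parent
    joint.children = [target, Node(leaf_label)]
    for c in joint.children:
        c.parent = joint
    if parent is None:
        joint.parent = None
        return joint, joint
    idx = parent.children.index(target)
    parent.children[idx] = joint
    joint.parent = parent
    return root, joint


def _remove_joint(root: Node, joint: Node, target: Node):
    """Undo :func:`_insert_above`; returns the restored root."""
    parent = joint.parent
    target.parent = parent
    if parent is None:
        return target
    idx = parent.children.index(joint)
    parent.children[idx] = target
    return root


def _greedy_addition(
    order: Sequence[str], states: np.ndarray, row: dict[str, int]
) -> tuple[Node, int]:
    root = _two_taxon_tree(order[0], order[1])
    for label in order[2:]:
        best = None
        for target in _all_nodes(root):
            root, joint = _insert_above(root, target, label)
            s = _stem_score(root, states, row)
            root = _remove_joint(root, joint, target)
            if best is None or s < best[0]:
                best = (s, target)
        root, _ = _insert_above(root, best[1], label)
    return root, _stem_score(root, states, row)


def _bab_taxon_order(matrix: PresenceMatrix, states, row) -> list[str]:
    """Decreasing per-taxon impact: taxa whose removal from the greedy tree
    changes the score most come first (tighter early bounds)."""
    species = list(matrix.species)
    greedy_root, greedy_score = _greedy_addition(species, states, row)
    greedy = Phylo(_copy(greedy_root))
    impact = {}
    for sp in species:
        pruned = greedy.prune_leaf(sp)
        impact[sp] = greedy_score - _stem_score(pruned.root, states, row)
    return sorted(species, key=lambda s: (-impact[s], species.index(s)))


def _copy(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add_child(_copy(child))
    return new


def branch_and_bound(
    matrix: PresenceMatrix, max_exact_taxa: int = 12, seed: int = 0
) -> SearchResult:
    """Exhaustive-equivalent search for ALL minimum-score rooted trees.

    The initial upper bound comes from greedy stepwise addition; partial
    trees whose restricted (stem-convention) score already exceeds the
    incumbent cannot complete to a better tree and are pruned.  ``seed`` is
    accepted for interface symmetry; the search is deterministic.
    """
    n = len(matrix.species)
    if n < 2:
        raise ValueError("need at least two species")
    if n > max_exact_taxa:
        raise ValueError(
            f"{n} taxa exceeds max_exact_taxa={max_exact_taxa}; "
            "use heuristic_search"
        )
    states, row = _prepare(matrix)
    order = _bab_taxon_order(matrix, states, row)
    _, incumbent = _greedy_addition(order, states, row)

    best_keys: set[str] = set()
    best_trees: list[Phylo] = []
    evaluated = 0
    best_score = incumbent

    def recurse(root: Node, next_i: int):
        nonlocal best_score, evaluated, best_trees, best_keys
        evaluated += 1
        score = _stem_score(root, states, row)
        if score > best_score:
            return
        if next_i == len(order):
            if score < best_score:
                best_score = score
                best_trees, best_keys = [], set()
            tree = Phylo(_copy(root))
            key = tree.topology_key()
            if key not in best_keys:
                best_keys.add(key)
                best_trees.append(tree)
            return
        label = order[next_i]
        for target in _all_nodes(root):
            new_root, joint = _insert_above(root, target, label)
            recurse(new_root, next_i + 1)
            restored = _remove_joint(new_root, joint, target)
            root = restored

    recurse(_two_taxon_tree(order[0], order[1]), 2)
    best_trees.sort(key=lambda t: t.topology_key())
    final_score = tree_score(best_trees[0], matrix)
    return SearchResult(final_score, best_trees, evaluated, "exact")


def heuristic_search(
    matrix: PresenceMatrix, n_starts: int = 10, seed: int = 0
) -> SearchResult:
    """Random-addition stepwise trees refined by NNI hill climbing."""
    n = len(matrix.species)
    if n < 4:
        raise ValueError("need at least four species")
    states, row = _prepare(matrix)
    rng = np.random.default_rng(seed)
    species = list(matrix.species)

    best_score = None
    best_trees: list[Phylo] = []
    best_keys: set[str] = set()
    evaluated = 0

    for _start in range(n_starts):
        order = list(species)
        rng.shuffle(order)
        root, score = _greedy_addition(order, states, row)
        evaluated += 1
        improved = True
        while improved:
            improved = False
            best_move = None
            for node, sib_idx, child_idx in _nni_moves(root):
                _nni_apply(node, sib_idx, child_idx)
                s = _stem_score(root, states, row)
                evaluated += 1
                _nni_apply(node, sib_idx, child_idx)  # involution: undo
                if s < score and (best_move is None or s < best_move[0]):
                    best_move = (s, node, sib_idx, child_idx)
            if best_move is not None:
                score = best_move[0]
                _nni_apply(best_move[1], best_move[2], best_move[3])
                improved = True
        if best_score is None or score < best_score:
            best_score = score
            best_trees, best_keys = [], set()
        if score == best_score:
            tree = Phylo(_copy(root))
            key = tree.topology_key()
            if key not in best_keys:
                best_keys.add(key)
                best_trees.append(tree)

    best_trees.sort(key=lambda t: t.topology_key())
    final_score = tree_score(best_trees[0], matrix)
    return SearchResult(final_score, best_trees, evaluated, "heuristic")


def _nni_moves(root: Node):
    """All NNI moves on a rooted binary tree, as (node, sibling_idx, child_idx).

    For each internal non-root node X with sibling S and children C1, C2,
    swapping S with either child yields one neighbour."""
    for node in _all_nodes(root):
        if node is root or node.is_leaf():
            continue
        parent = node.parent
        if len(parent.children) != 2 or len(node.children) != 2:
            continue
        sib_idx = 1 - parent.children.index(node)
        for child_idx in (0, 1):
            yield node, sib_idx, child_idx


def _nni_apply(node: Node, sib_idx: int, child_idx: int):
    parent = node.parent
    sib = parent.children[sib_idx]
    child = node.children[child_idx]
    parent.children[sib_idx] = child
    child.parent = parent
    node.children[child_idx] = sib
    sib.parent = node


# ----------------------------------------------------------------- bootstrap


def bootstrap_consensus(
    matrix: PresenceMatrix,
    n_reps: int = 100,
    threshold: float = 0.5,
    seed: int = 0,
    max_exact_taxa: int = 12,
    n_starts: int = 10,
) -> ConsensusTree:
    """Gene-column bootstrap with majority-rule consensus.

    Each replicate resamples columns with replacement (same column count),
    reruns the search (exact when the taxon count allows, heuristic
    otherwise), and contributes one best tree — the first by canonical
    topology sort.  Support for a clade is the percentage of replicates
    containing it; clades above ``threshold`` (strict majority by default)
    are assembled greedily by descending support into the consensus.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.5 <= threshold < 1):
        raise ValueError("threshold must be in [0.5, 1)")
    rng = np.random.default_rng(seed)
    n_genes = len(matrix.genes)
    n = len(matrix.species)
    counts: dict[frozenset, int] = {}
    for rep in range(n_reps):
        idx = rng.integers(0, n_genes, size=n_genes)
        boot = matrix.resample_genes(idx)
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if n <= max_exact_taxa:
            result = branch_and_bound(boot, max_exact_taxa=max_exact_taxa)
        else:
            result = heuristic_search(boot, n_starts=n_starts, seed=rep_seed)
        tree = result.headline_tree
        for node in tree.postorder():
            if node is tree.root or node.is_leaf():
                continue
            clade = tree.clade(tree.branch_id(node))
            counts[clade] = counts.get(clade, 0) + 1

    all_leaves = frozenset(matrix.species)
    pct = {clade: 100.0 * c / n_reps for clade, c in counts.items()}
    candidates = sorted(
        (c for c in pct if pct[c] > threshold * 100.0),
        key=lambda c: (-pct[c], -len(c), sorted(c)),
    )
    accepted: list[frozenset] = []
    for clade in candidates:
        if all(
            clade <= other or other <= clade or not (clade & other)
            for other in accepted
        ):
            accepted.append(clade)

    tree = _tree_from_clades(sorted(all_leaves), accepted)
    supports = {}
    for node in tree.postorder():
        if node is tree.root or node.is_leaf():
            continue
        supports[tree.branch_id(node)] = pct[tree.clade(tree.branch_id(node))]
    return ConsensusTree(tree, supports)


def _tree_from_clades(leaves: Sequence[str], clades: Sequence[frozenset]) -> Phylo:
    """Assemble the rooted tree containing exactly the given nested clades."""
    ordered = sorted(set(clades), key=len, reverse=True)
    root = Node(None)
    node_of: dict[frozenset, Node] = {frozenset(leaves): root}
    containers = [frozenset(leaves)]
    for clade in ordered:
        parent_set = min(
            (c for c in containers if clade < c), key=len
        )
        node = Node(None)
        node_of[parent_set].add_child(node)
        node_of[clade] = node
        containers.append(clade)
    for leaf in leaves:
        parent_set = min((c for c in containers if leaf in c), key=len)
        node_of[parent_set].add_child(Node(leaf))
    return Phylo(root)
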