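"""Rooted trees and the Dollo parsimony engine.

Under the Dollo criterion a binary character (gene present = 1, lost = 0)
originates exactly once (a single 0→1 gain) and may then be lost (1→0) on
as many branches as needed, but a loss is irreversible.  The optimal
explanation of a leaf pattern therefore minimises the number of loss
branches.  With the gain pinned to the root — the natural setting when the
character universe is defined by an outgroup reference genome — the minimum
equals the number of maximal clades whose observed leaves are all 0:
each such clade is covered by one loss on its stem, and its sibling
lineages contain a 1 that forbids placing the loss any higher.

Missing data ('?') is resolved in whichever direction avoids losses:
a clade consisting entirely of missing leaves stays present, and missing
leaves inside an all-0 clade join the loss.

Trees are rooted, may be multifurcating, and carry optional branch lengths
(millions of years in this package's fixtures).  Every branch is addressed
by a stable identifier keyed to its child node: the leaf label for terminal
branches, the internal node's own label when the newick provides one, and
otherwise the sorted '|'-joined leaf set of the clade below it — so loss
maps survive re-serialisation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "ROOT_BRANCH",
    "Node",
    "Phylo",
    "DolloFit",
    "read_newick",
    "write_newick",
    "dollo_fit",
    "tree_score",
    "per_gene_losses",
    "collapse_branch",
]

#: integer code for a '?' (unknown) leaf state in scoring arrays
MISSING = -1

#: marker used as ``gain_branch`` when the gain sits at the root
ROOT_BRANCH = "ROOT"


class Node:
    """A tree node; the edge to its parent is 'the branch of' this node."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None, children=None):
        self.label = label
        self.length = length
        self.children = list(children) if children else []
        self.parent = None
        for child in self.children:
            child.parent = self

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> None:
        node.parent = self
        self.children.append(node)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Phylo:
    """A rooted phylogeny with stable branch identifiers.

    Wraps a :class:`Node` structure and indexes it (postorder list, leaf
    order, clade leaf sets, branch ids).  Mutating the node structure
    directly requires re-instantiation; all public operations return new
    trees.
    """

    def __init__(self, root: Node):
        self.root = root
        self._reindex()

    # ------------------------------------------------------------------ index
    def _reindex(self) -> None:
        order: list[Node] = []
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        self._postorder = order

        leaves = [n for n in order if n.is_leaf()]
        labels = [n.label for n in leaves]
        if any(lab in (None, "") for lab in labels):
            raise ValueError("every leaf must carry a non-empty label")
        dupes = {lab for lab in labels if labels.count(lab) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
        # postorder visits leaves left-to-right, i.e. newick order
        self._leaves = leaves

        self._leafset: dict[Node, frozenset] = {}
        for node in order:
            if node.is_leaf():
                self._leafset[node] = frozenset((node.label,))
            else:
                self._leafset[node] = frozenset().union(
                    *(self._leafset[c] for c in node.children)
                )

        self._branch_id: dict[Node, str] = {}
        self._by_branch: dict[str, Node] = {}
        for node in order:
            if node is self.root:
                bid = ROOT_BRANCH
            elif node.is_leaf():
                bid = node.label
            elif node.label:
                bid = node.label
            else:
                bid = "|".join(sorted(self._leafset[node]))
            if bid in self._by_branch:
                raise ValueError(f"branch identifier collision: {bid!r}")
            self._branch_id[node] = bid
            self._by_branch[bid] = node

    # ------------------------------------------------------------- accessors
    def postorder(self) -> Sequence[Node]:
        return self._postorder

    def leaves(self) -> Sequence[Node]:
        return self._leaves

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self._leaves]

    def n_leaves(self) -> int:
        return len(self._leaves)

    def branch_id(self, node: Node) -> str:
        return self._branch_id[node]

    def node(self, branch_id: str) -> Node:
        try:
            return self._by_branch[branch_id]
        except KeyError:
            raise KeyError(f"no branch {branch_id!r} in tree") from None

    def has_branch(self, branch_id: str) -> bool:
        return branch_id in self._by_branch

    def branch_ids(self, include_root: bool = False) -> list[str]:
        return [
            self._branch_id[n]
            for n in self._postorder
            if include_root or n is not self.root
        ]

    def internal_branch_ids(self) -> list[str]:
        """Branches above internal (non-root, non-leaf) nodes."""
        return [
            self._branch_id[n]
            for n in self._postorder
            if n is not self.root and not n.is_leaf()
        ]

    def terminal_branch_ids(self) -> list[str]:
        return [n.label for n in self._leaves]

    def clade(self, branch_id: str) -> frozenset:
        return self._leafset[self.node(branch_id)]

    def branch_lengths(self) -> dict[str, float]:
        """branch id -> length for every non-root branch that has one."""
        out = {}
        for node in self._postorder:
            if node is not self.root and node.length is not None:
                out[self._branch_id[node]] = float(node.length)
        return out

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        missing = want - self._leafset[self.root]
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        best = self.root
        improved = True
        while improved:
            improved = False
            for child in best.children:
                if want <= self._leafset[child]:
                    best = child
                    improved = True
                    break
        return best

    # ------------------------------------------------------------ operations
    def copy(self) -> "Phylo":
        return Phylo(_copy_nodes(self.root))

    def prune_leaf(self, label: str) -> "Phylo":
        """Remove one leaf and suppress the resulting unary node."""
        root = _copy_nodes(self.root)
        leaf = _find_leaf(root, label)
        if leaf is None:
            raise KeyError(f"no leaf {label!r}")
        parent = leaf.parent
        if parent is None:
            raise ValueError("cannot prune the only node")
        parent.children.remove(leaf)
        if len(parent.children) == 1:
            only = parent.children[0]
            grand = parent.parent
            if grand is None:
                only.parent = None
                if only.length is not None or parent.length is not None:
                    only.length = (only.length or 0.0) + (parent.length or 0.0)
                root = only
            else:
                if only.length is not None or parent.length is not None:
                    only.length = (only.length or 0.0) + (parent.length or 0.0)
                idx = grand.children.index(parent)
                grand.children[idx] = only
                only.parent = grand
        return Phylo(root)

    def topology_key(self) -> str:
        """Canonical label-sorted, length-free newick; equal iff same topology."""
        def fmt(node: Node) -> str:
            if node.is_leaf():
                return node.label
            return "(" + ",".join(sorted(fmt(c) for c in node.children)) + ")"

        return fmt(self.root) + ";"

    def __eq__(self, other):
        return isinstance(other, Phylo) and self.topology_key() == other.topology_key()

    def __hash__(self):
        return hash(self.topology_key())

    def newick(self, lengths: bool = True, internal_labels: bool = True) -> str:
        return write_newick(self, lengths=lengths, internal_labels=internal_labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylo":
        return read_newick(text)


def _copy_nodes(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add_child(_copy_nodes(child))
    return new


def _find_leaf(root: Node, label: str):
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf() and node.label == label:
            return node
        stack.extend(node.children)
    return None


# ---------------------------------------------------------------- newick i/o

_PLAIN_LABEL = re.compile(r"[\w.\-|]+\Z")


def _fmt_label(label: str) -> str:
    if _PLAIN_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _fmt_length(x: float) -> str:
    return format(float(x), "g")


def read_newick(text: str) -> Phylo:
    """Parse a (possibly multifurcating) rooted newick string or file text."""
    import dendropy

    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted",
        )
    except Exception as exc:
        raise ValueError(f"could not parse newick: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(label, dnode.edge.length)
        node = Node(dnode.label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Phylo(convert(tree.seed_node))


def write_newick(tree: Phylo, lengths: bool = True, internal_labels: bool = True) -> str:
    def fmt(node: Node) -> str:
        if node.is_leaf():
            s = _fmt_label(node.label)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if internal_labels and node.label:
                s += _fmt_label(node.label)
        if lengths and node.length is not None:
            s += ":" + _fmt_length(node.length)
        return s

    return fmt(tree.root) + ";"


# ------------------------------------------------------------- dollo scoring


@dataclass(frozen=True)
class DolloFit:
    """Optimal Dollo explanation of one character on one tree."""

    losses: int
    loss_branches: frozenset
    gain_branch: str | None

    def __post_init__(self):
        if self.losses != len(self.loss_branches):
            raise ValueError("losses must equal |loss_branches|")


def _states_matrix(
    tree: Phylo, matrix_states: np.ndarray, matrix_species: Sequence[str]
) -> np.ndarray:
    """Reorder a species × gene state array into the tree's leaf order."""
    tree_labels = tree.leaf_labels
    mat_set, tree_set = set(matrix_species), set(tree_labels)
    if mat_set != tree_set:
        only_m = sorted(mat_set - tree_set)
        only_t = sorted(tree_set - mat_set)
        raise ValueError(
            f"species mismatch: only in matrix {only_m}, only in tree {only_t}"
        )
    row = {s: i for i, s in enumerate(matrix_species)}
    idx = np.array([row[lab] for lab in tree_labels])
    return np.asarray(matrix_states, dtype=np.int8)[idx]


def _node_status(tree: Phylo, states: np.ndarray):
    """Per node: has1 (subtree contains an observed 1), allmiss (all '?')."""
    has1: dict[Node, np.ndarray] = {}
    allmiss: dict[Node, np.ndarray] = {}
    leaf_row = {leaf: i for i, leaf in enumerate(tree.leaves())}
    for node in tree.postorder():
        if node.is_leaf():
            row = states[leaf_row[node]]
            has1[node] = row == 1
            allmiss[node] = row == MISSING
        else:
            has1[node] = np.logical_or.reduce([has1[c] for c in node.children])
            allmiss[node] = np.logical_and.reduce([allmiss[c] for c in node.children])
    return has1, allmiss


def per_gene_losses(
    tree: Phylo,
    matrix_states: np.ndarray,
    matrix_species: Sequence[str],
    *,
    allzero_policy: str = "children",
    return_loss_masks: bool = False,
):
    """Vectorised Dollo loss counts for every column, gain pinned to the root.

    ``matrix_states`` is species × gene with entries in {1, 0, -1('?')}.

    ``allzero_policy`` governs characters whose observed leaves are all 0:
    ``"children"`` (the public convention) charges one loss per root child
    containing an observed 0; ``"stem"`` charges a single loss on a virtual
    root edge.  The stem variant is monotone under taxon restriction and is
    what the branch-and-bound search prunes with.

    Returns an int32 vector of per-gene loss counts, plus (optionally) an
    ordered mapping branch id -> boolean gene mask of loss placements (the
    stem policy uses :data:`ROOT_BRANCH` as the key for all-0 characters).
    """
    if allzero_policy not in ("children", "stem"):
        raise ValueError(f"unknown allzero_policy {allzero_policy!r}")
    states = _states_matrix(tree, matrix_states, matrix_species)
    n_genes = states.shape[1]
    has1, allmiss = _node_status(tree, states)
    root = tree.root
    losses = np.zeros(n_genes, dtype=np.int32)
    masks: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        if node is root:
            continue
        parent = node.parent
        all0 = ~(has1[node] | allmiss[node])
        if parent is root and allzero_policy == "children":
            # counts both under a 1-root (parent rule) and an all-0 root
            mask = all0 & ~allmiss[root]
        else:
            mask = all0 & has1[parent]
        losses += mask
        if return_loss_masks:
            masks[tree.branch_id(node)] = mask
    if allzero_policy == "stem":
        root_all0 = ~(has1[root] | allmiss[root])
        losses += root_all0
        if return_loss_masks:
            masks[ROOT_BRANCH] = root_all0
    if return_loss_masks:
        return losses, masks
    return losses


def _char_to_column(tree: Phylo, char: Mapping[str, object]) -> np.ndarray:
    labels = tree.leaf_labels
    extra = set(char) - set(labels)
    if extra:
        raise ValueError(f"character references leaves not in tree: {sorted(extra)}")
    col = np.empty((len(labels), 1), dtype=np.int8)
    for i, lab in enumerate(labels):
        state = char.get(lab, "?")
        if state in (0, 1):
            col[i, 0] = state
        elif state in ("?", None, MISSING):
            col[i, 0] = MISSING
        else:
            raise ValueError(f"invalid state {state!r} for leaf {lab!r}")
    return col


def dollo_fit(
    tree: Phylo, char: Mapping[str, object], root_present: bool = True
) -> DolloFit:
    """Minimum-loss Dollo explanation of a single character.

    With ``root_present`` the gain sits at the root; otherwise the gain is
    placed on the branch above the MRCA of the observed-1 leaves (a
    character with no observed 1 then needs no events at all).
    """
    col = _char_to_column(tree, char)
    if root_present:
        losses, masks = per_gene_losses(
            tree, col, tree.leaf_labels, return_loss_masks=True
        )
        branches = frozenset(b for b, m in masks.items() if m[0])
        return DolloFit(int(losses[0]), branches, ROOT_BRANCH)

    states = col  # already in tree leaf order
    has1, allmiss = _node_status(tree, states)
    one_leaves = [
        leaf.label for leaf, s in zip(tree.leaves(), states[:, 0]) if s == 1
    ]
    if not one_leaves:
        return DolloFit(0, frozenset(), None)
    gain = tree.mrca(one_leaves)
    branches = []
    stack = list(gain.children)
    while stack:
        node = stack.pop()
        all0 = not (has1[node][0] or allmiss[node][0])
        if all0 and has1[node.parent][0]:
            branches.append(tree.branch_id(node))
        stack.extend(node.children)
    gain_bid = ROOT_BRANCH if gain is tree.root else tree.branch_id(gain)
    return DolloFit(len(branches), frozenset(branches), gain_bid)


def tree_score(tree: Phylo, matrix, root_present: bool = True) -> int:
    """Total Dollo loss count of a presence matrix on a tree.

    ``matrix`` is any object with ``species`` (list), ``genes`` (list) and
    ``states`` (species × gene array) attributes — see
    :class:`dolloloss.toga_io.PresenceMatrix`.
    """
    if root_present:
        return int(per_gene_losses(tree, matrix.states, matrix.species).sum())
    total = 0
    for j in range(len(matrix.genes)):
        char = {s: int(matrix.states[i, j]) for i, s in enumerate(matrix.species)}
        total += dollo_fit(tree, char, root_present=False).losses
    return total


def collapse_branch(tree: Phylo, branch_id: str) -> Phylo:
    """Collapse one internal branch into a polytomy (lengths discarded).

    The child node of the branch is removed and its children re-attach to
    its parent at the same position; the result is scoreable by
    :func:`dollo_fit` with hard-polytomy semantics.
    """
    new = tree.copy()
    node = new.node(branch_id)
    if node.is_leaf():
        raise ValueError(f"branch {branch_id!r} is terminal; cannot collapse")
    if node is new.root:
        raise ValueError("cannot collapse the root")
    parent = node.parent
    idx = parent.children.index(node)
    for child in node.children:
        child.parent = parent
    parent.children[idx : idx + 1] = node.children
    return Phylo(new.root)
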