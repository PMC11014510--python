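"""Naive reference implementations used for validation.

These routines compute the same quantities as the optimised code paths by
exhaustive enumeration or exact rational arithmetic.  They are deliberately
slow and independent of the main implementations, and exist so that tests
and the validation harness can cross-check results on small instances.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb
from typing import Iterator, Mapping, Sequence

from .dollo_core import MISSING, Node, Phylo

__all__ = [
    "dollo_score_bruteforce",
    "all_rooted_binary_trees",
    "hypergeom_sf_exact",
]


def dollo_score_bruteforce(
    tree: Phylo, char: Mapping[str, object], root_present: bool = True
) -> int:
    """Minimum Dollo loss count by enumerating all node-state assignments.

    Every internal node (and every '?' leaf) is assigned 0 or 1; an
    assignment is admissible if it contains no 0→1 edge except a single
    gain (none at all when the root is forced present).  The score is the
    minimum number of 1→0 edges over admissible assignments.
    """
    nodes = list(tree.postorder())
    fixed: dict[Node, int] = {}
    free: list[Node] = []
    for node in nodes:
        if node.is_leaf():
            state = char.get(node.label, "?")
            if state in (0, 1):
                fixed[node] = int(state)
            elif state in ("?", None, MISSING):
                free.append(node)
            else:
                raise ValueError(f"invalid state {state!r}")
        else:
            free.append(node)

    root = tree.root
    best = None
    for combo in itertools.product((0, 1), repeat=len(free)):
        assign = dict(fixed)
        assign.update(zip(free, combo))
        if root_present and assign[root] != 1:
            continue
        gains = losses = 0
        for node in nodes:
            if node is root:
                continue
            ps, cs = assign[node.parent], assign[node]
            if ps == 0 and cs == 1:
                gains += 1
            elif ps == 1 and cs == 0:
                losses += 1
        if root_present:
            if gains:
                continue
        else:
            # single origin: root birth counts as the one gain
            if gains + assign[root] > 1:
                continue
        if best is None or losses < best:
            best = losses
    assert best is not None
    return best


def all_rooted_binary_trees(labels: Sequence[str]) -> Iterator[Phylo]:
    """Yield every rooted binary labeled topology on the given leaves.

    Generated by stepwise addition: each (2k-3)!! topology appears exactly
    once.  Counts: 1, 3, 15, 105, 945, 10395 for 2..7 leaves.
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least two leaves")

    def preorder(root: Node) -> list[Node]:
        out, stack = [], [root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def build(tree_labels: Sequence[str]):
        if len(tree_labels) == 2:
            yield Node(None, None, [Node(tree_labels[0]), Node(tree_labels[1])])
            return
        new_label = tree_labels[-1]
        for partial in build(tree_labels[:-1]):
            n_positions = 2 * (len(tree_labels) - 1) - 1  # all nodes of partial
            for i in range(n_positions):
                root = _deep_copy(partial)
                target = preorder(root)[i]
                joint = Node(None, None, [target, Node(new_label)])
                parent = None if target is root else _parent_in(root, target)
                # _deep_copy drops parent links; recompute via search
                if parent is None:
                    yield joint
                else:
                    idx = parent.children.index(target)
                    parent.children[idx] = joint
                    joint.parent = parent
                    yield root

    def _parent_in(root: Node, target: Node):
        stack = [root]
        while stack:
            node = stack.pop()
            for child in node.children:
                if child is target:
                    return node
                stack.append(child)
        return None

    for root in build(labels):
        yield Phylo(_deep_copy(root))


def _deep_copy(node: Node) -> Node:
    new = Node(node.label, node.length)
    for child in node.children:
        new.add_child(_deep_copy(child))
    return new


def hypergeom_sf_exact(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    if k <= 0:
        return Fraction(1)
    total = comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(K, n) + 1):
        acc += Fraction(comb(K, x) * comb(N - K, n - x), total)
    return acc
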