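"""Simulate gene loss along a rooted tree, with full ground truth.

The generator implements exactly the process the Dollo analysis assumes:
every gene is present in the root ancestor and, walking each branch
top-down, a gene still present at the parent is lost on branch *b* with
probability ``1 - exp(-base_rate * multiplier_b * length_b)``; once lost, a
gene stays lost in that whole subtree (irreversibility).  Parallel loss in
disjoint subtrees (homoplasy) arises naturally and is what makes the
reconstruction tests non-trivial.  Branch multipliers model rate bursts
(e.g. a stem lineage with an elevated loss rate).

The module also builds gene-set collections with designated sets enriched
for losses on a focal branch (fixtures for the over-representation stage),
writes loss-summary files in the TSV layout :mod:`dolloloss.toga_io`
parses, and ships a 17-leaf Atlantogenata-shaped fixture tree whose branch
lengths (in millions of years) are plausible but synthetic.

Default study-like conditions, used by the shipped fixture configs:
2,000 genes at a base rate of 8e-4 losses/gene/My, which yields a few
percent of genes lost per species — the order of magnitude genome-wide
ortholog screens report — while keeping simulation batteries fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dollo_core import Phylo, read_newick
from .toga_io import PresenceMatrix

__all__ = [
    "LossSimConfig",
    "SimTruth",
    "simulate_losses",
    "simulate_enriched_sets",
    "write_fixture_files",
    "atlantogenata_tree",
    "atlantogenata_species_tree",
    "burst_fixture_config",
    "clade_fixture",
    "clade_marker_matrix",
]

DEFAULT_BASE_RATE = 8e-4  # losses per gene per My
DEFAULT_N_GENES = 2000


@dataclass
class LossSimConfig:
    tree: Phylo
    n_genes: int = DEFAULT_N_GENES
    base_rate: float = DEFAULT_BASE_RATE
    branch_multipliers: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    gene_prefix: str = "G"

    def __post_init__(self):
        if self.base_rate < 0:
            raise ValueError("base_rate must be >= 0")
        if any(m < 0 for m in self.branch_multipliers.values()):
            raise ValueError("branch multipliers must be >= 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        unknown = set(self.branch_multipliers) - set(self.tree.branch_ids())
        if unknown:
            raise ValueError(f"multipliers name unknown branches: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Realised simulation with its generating events."""

    tree: Phylo
    gene_names: list[str]
    gene_loss_branches: list[tuple[str, ...]]  # branches each gene was lost on
    branch_counts: dict[str, int]
    matrix: PresenceMatrix

    def focal_lost_genes(self, branch_id: str) -> set[str]:
        return {
            g
            for g, branches in zip(self.gene_names, self.gene_loss_branches)
            if branch_id in branches
        }

    def exclusive_loss_counts(self) -> dict[str, int]:
        """Per branch: genes whose ONLY loss event is that branch."""
        out = {b: 0 for b in self.tree.branch_ids()}
        for branches in self.gene_loss_branches:
            if len(branches) == 1:
                out[branches[0]] += 1
        return out


def simulate_losses(cfg: LossSimConfig) -> SimTruth:
    """Run the irreversible-loss process for every gene independently."""
    tree = cfg.tree
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    present: dict = {tree.root: np.ones(n, dtype=bool)}
    loss_events: dict[str, np.ndarray] = {}
    # preorder traversal (parents before children)
    for node in reversed(list(tree.postorder())):
        if node is tree.root:
            continue
        if node.length is None:
            raise ValueError(
                f"branch {tree.branch_id(node)!r} has no length; "
                "the simulator needs lengths on every branch"
            )
        bid = tree.branch_id(node)
        mult = cfg.branch_multipliers.get(bid, 1.0)
        p_loss = 1.0 - math.exp(-cfg.base_rate * mult * node.length)
        parent_present = present[node.parent]
        lost_here = parent_present & (rng.random(n) < p_loss)
        present[node] = parent_present & ~lost_here
        loss_events[bid] = lost_here

    gene_names = [f"{cfg.gene_prefix}{i:05d}" for i in range(n)]
    per_gene: list[list[str]] = [[] for _ in range(n)]
    branch_counts: dict[str, int] = {}
    for node in reversed(list(tree.postorder())):  # stable, preorder
        if node is tree.root:
            continue
        bid = tree.branch_id(node)
        mask = loss_events[bid]
        branch_counts[bid] = int(mask.sum())
        for i in np.flatnonzero(mask):
            per_gene[i].append(bid)

    leaves = tree.leaves()
    states = np.stack([present[leaf].astype(np.int8) for leaf in leaves])
    matrix = PresenceMatrix(tree.leaf_labels, gene_names, states)
    return SimTruth(
        tree, gene_names, [tuple(b) for b in per_gene], branch_counts, matrix
    )


def simulate_enriched_sets(
    truth: SimTruth,
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 60),
    n_enriched: int = 2,
    focal_branch: str = "",
    boost: float = 5.0,
    seed: int = 0,
):
    """Partition genes into annotation sets; designated sets over-sample
    genes lost on a focal branch.

    Returns ``(collection, designated)`` where ``collection`` is a
    :class:`dolloloss.enrichment.GeneSetCollection` and ``designated`` the
    list of term ids built to be enriched.  Designated sets are filled with
    focal-branch-lost genes until their focal-loss fraction reaches
    ``boost`` times the background fraction (or the pool runs out, with a
    warning stating the achieved fold).
    """
    from .enrichment import GeneSetCollection

    if boost <= 1:
        raise ValueError("boost must exceed 1")
    if focal_branch not in truth.tree.branch_ids():
        raise ValueError(f"focal branch {focal_branch!r} not in tree")
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    genes = list(truth.gene_names)
    focal = truth.focal_lost_genes(focal_branch)
    f0 = len(focal) / len(genes)
    target_frac = min(1.0, boost * f0)

    focal_pool = [g for g in genes if g in focal]
    other_pool = [g for g in genes if g not in focal]
    rng.shuffle(focal_pool)
    rng.shuffle(other_pool)

    sets: dict[str, tuple[str, list[str]]] = {}
    designated = []
    exhausted_fold = None
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        term = f"SET{s:03d}"
        if s < n_enriched:
            want_focal = max(1, math.ceil(target_frac * size))
            take_focal = min(want_focal, len(focal_pool))
            members = [focal_pool.pop() for _ in range(take_focal)]
            if take_focal < want_focal:
                achieved = (take_focal / size) / f0 if f0 else 0.0
                exhausted_fold = achieved
            members += [other_pool.pop() for _ in range(min(size - take_focal,
                                                            len(other_pool)))]
            designated.append(term)
            desc = f"designated (focal={focal_branch}, boost={boost:g})"
        else:
            pool_take = min(size, len(other_pool))
            members = [other_pool.pop() for _ in range(pool_take)]
            if len(members) < size and focal_pool:
                members += [focal_pool.pop()
                            for _ in range(min(size - len(members), len(focal_pool)))]
            desc = "background set"
        if not members:
            break
        sets[term] = (desc, members)
    if exhausted_fold is not None:
        warnings.warn(
            f"focal-branch loss pool exhausted; achieved fold {exhausted_fold:.2f} "
            f"instead of {boost:g}",
            stacklevel=2,
        )
    return GeneSetCollection(sets), designated


def write_fixture_files(truth: SimTruth, out_dir) -> list[Path]:
    """Emit per-species loss-summary TSVs plus ground-truth tables.

    Statuses are "L" for lost, "I" otherwise; parsing the files with
    :mod:`dolloloss.toga_io` and assembling reproduces ``truth.matrix``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i, sp in enumerate(truth.matrix.species):
        path = out / f"loss_summ.{sp}.tsv"
        with path.open("w") as fh:
            for j, gene in enumerate(truth.matrix.genes):
                status = "I" if truth.matrix.states[i, j] == 1 else "L"
                fh.write(f"GENE\t{gene}\t{status}\n")
        written.append(path)

    gl = out / "truth_gene_losses.tsv"
    with gl.open("w") as fh:
        fh.write("gene\tloss_branches\n")
        for gene, branches in zip(truth.gene_names, truth.gene_loss_branches):
            fh.write(f"{gene}\t{','.join(branches)}\n")
    written.append(gl)

    bc = out / "truth_branch_counts.tsv"
    with bc.open("w") as fh:
        fh.write("branch\tn_losses\n")
        for bid, count in truth.branch_counts.items():
            fh.write(f"{bid}\t{count}\n")
    written.append(bc)
    return written


# ------------------------------------------------------------------ fixtures


def atlantogenata_tree() -> Phylo:
    """The packaged 17-species Atlantogenata-shaped tree.

    Topology follows the accepted species phylogeny (Xenarthra sister to
    Afrotheria; Paenungulata resolved as hyrax + Tethytheria); branch
    lengths are synthetic but plausibly scaled divergence times in My.
    """
    from importlib.resources import files

    text = files("dolloloss").joinpath("data/atlantogenata_synthetic.nwk").read_text()
    return read_newick(text)


def atlantogenata_species_tree() -> Phylo:
    """Fixture tree with Paenungulata collapsed to a hard polytomy
    (hyrax / elephants / sea cows), the form used for ancestral
    reconstruction when the Paenungulate branching order is treated as
    unresolved."""
    from .dollo_core import collapse_branch

    return collapse_branch(atlantogenata_tree(), "Tethytheria")


def burst_fixture_config(
    seed: int = 0,
    n_genes: int = DEFAULT_N_GENES,
    base_rate: float = DEFAULT_BASE_RATE,
    burst_branch: str = "Afrotheria",
    burst_factor: float = 5.0,
) -> LossSimConfig:
    """Study-shaped simulation: 17 taxa, one stem branch with a loss-rate
    burst (default 5× on the Afrotheria stem)."""
    return LossSimConfig(
        tree=atlantogenata_tree(),
        n_genes=n_genes,
        base_rate=base_rate,
        branch_multipliers={burst_branch: burst_factor},
        seed=seed,
    )


CLADE_FIXTURE_CLADES = ("Cingulata", "Pilosa", "Paenungulata", "Afroinsectiphilia")


def clade_fixture(seed: int = 0, n_genes: int = 3000, stem_loss_prob: float = 0.35):
    """Clade-structured loss simulation for the clustering tests.

    Four disjoint clades covering all 17 leaves each receive a stem-branch
    multiplier calibrated so ~``stem_loss_prob`` of genes are lost on each
    clade stem (a block of shared derived losses per clade), over a low
    base rate.  Returns ``(truth, true_labels)`` with ``true_labels`` the
    species → clade-index ground truth partition.
    """
    tree = atlantogenata_tree()
    base = 3e-4
    lengths = tree.branch_lengths()
    mult = {
        clade: -math.log(1.0 - stem_loss_prob) / (base * lengths[clade])
        for clade in CLADE_FIXTURE_CLADES
    }
    cfg = LossSimConfig(
        tree=tree, n_genes=n_genes, base_rate=base, branch_multipliers=mult, seed=seed
    )
    truth = simulate_losses(cfg)
    labels = {}
    for k, clade in enumerate(CLADE_FIXTURE_CLADES):
        for leaf in tree.clade(clade):
            labels[leaf] = k
    return truth, labels


def clade_marker_matrix(
    tree: Phylo,
    per_branch: int = 20,
    branches: Sequence[str] | None = None,
    n_invariant: int = 0,
    terminal_per_leaf: int = 0,
) -> PresenceMatrix:
    """Deterministic matrix of exclusive clade-loss characters.

    For each chosen branch, ``per_branch`` characters are 0 exactly at the
    leaves below it and 1 elsewhere — the strongest possible synapomorphic
    signal for that branch.  Optional invariant (all-1) columns and
    single-species loss columns can be appended.
    """
    if branches is None:
        branches = tree.internal_branch_ids()
    labels = tree.leaf_labels
    cols, names = [], []
    for bid in branches:
        clade = tree.clade(bid)
        col = np.array([0 if lab in clade else 1 for lab in labels], dtype=np.int8)
        for r in range(per_branch):
            cols.append(col)
            names.append(f"{bid}.marker{r}")
    for leaf_i, lab in enumerate(labels):
        col = np.ones(len(labels), dtype=np.int8)
        col[leaf_i] = 0
        for r in range(terminal_per_leaf):
            cols.append(col.copy())
            names.append(f"{lab}.private{r}")
    for r in range(n_invariant):
        cols.append(np.ones(len(labels), dtype=np.int8))
        names.append(f"invariant{r}")
    states = np.stack(cols, axis=1) if cols else np.zeros((len(labels), 0), np.int8)
    return PresenceMatrix(list(labels), names, states)
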