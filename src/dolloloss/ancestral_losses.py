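"""Ancestral gene-loss reconstruction on a fixed species tree.

With every gene forced present in the common ancestor (the natural setting
when the character universe comes from an outgroup reference genome), the
Dollo-optimal explanation of each gene places its losses on the stems of
the maximal all-lost clades.  Aggregating over genes gives per-branch loss
tallies — the "number of genes lost in each lineage" annotation of a
species tree — and a gene × branch event table.

Genes absent from every species are reference-private artifacts under this
model (they incur one loss per root child); they are counted but also
reported separately.

The branch-rate regression asks whether per-branch loss counts simply
scale with branch duration (in My): Pearson correlation with a two-sided
t test, an OLS fit, and branches with |internally studentized residual|
above a threshold (default 2) flagged as loss-rate outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dollo_core import Phylo, per_gene_losses, tree_score
from .toga_io import PresenceMatrix

__all__ = [
    "LossReconstruction",
    "BranchRegression",
    "reconstruct_losses",
    "branch_regression",
    "foreground_from_reconstruction",
]


@dataclass
class LossReconstruction:
    tree: Phylo
    genes: list[str]
    gene_loss_branches: dict[str, frozenset]  # gene -> branches carrying a loss
    branch_counts: dict[str, int]  # branch id -> number of genes lost there
    branch_genes: dict[str, list[str]]  # branch id -> genes lost there
    allzero_genes: list[str]  # genes observed lost in every species

    @property
    def total_losses(self) -> int:
        return sum(self.branch_counts.values())

    def branch_table(self) -> pd.DataFrame:
        """Gene × branch 0/1 event table (the per-branch source-data analogue)."""
        branches = list(self.branch_counts)
        data = np.zeros((len(self.genes), len(branches)), dtype=np.int8)
        col = {b: j for j, b in enumerate(branches)}
        for i, gene in enumerate(self.genes):
            for b in self.gene_loss_branches[gene]:
                data[i, col[b]] = 1
        return pd.DataFrame(data, index=self.genes, columns=branches)

    def summary(self) -> pd.DataFrame:
        lengths = self.tree.branch_lengths()
        rows = []
        internal = set(self.tree.internal_branch_ids())
        for bid, count in self.branch_counts.items():
            rows.append(
                {
                    "branch": bid,
                    "n_losses": count,
                    "length_my": lengths.get(bid, np.nan),
                    "internal": bid in internal,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class BranchRegression:
    table: pd.DataFrame  # branch, length_my, n_losses, std_residual, outlier
    r: float
    r2: float
    p_value: float
    slope: float
    intercept: float
    outlier_branches: list[str]


def reconstruct_losses(tree: Phylo, matrix: PresenceMatrix) -> LossReconstruction:
    """Per-gene Dollo loss placement (gain fixed at the root) and per-branch
    totals; polytomies are scored directly (hard-polytomy semantics)."""
    losses, masks = per_gene_losses(
        tree, matrix.states, matrix.species, return_loss_masks=True
    )
    genes = list(matrix.genes)
    gene_branches: dict[str, set] = {g: set() for g in genes}
    branch_counts: dict[str, int] = {}
    branch_genes: dict[str, list[str]] = {}
    for bid, mask in masks.items():
        hit = np.flatnonzero(mask)
        branch_counts[bid] = int(mask.sum())
        branch_genes[bid] = [genes[i] for i in hit]
        for i in hit:
            gene_branches[genes[i]].add(bid)
    allzero = [
        genes[j] for j in np.flatnonzero(matrix.states.sum(axis=0) == 0)
    ]
    return LossReconstruction(
        tree,
        genes,
        {g: frozenset(b) for g, b in gene_branches.items()},
        branch_counts,
        branch_genes,
        allzero,
    )


def branch_regression(
    rec: LossReconstruction,
    lengths: Mapping[str, float] | None = None,
    include_terminal: bool = True,
    resid_threshold: float = 2.0,
) -> BranchRegression:
    """Regress per-branch loss counts on branch durations.

    ``lengths`` defaults to the reconstruction tree's own branch lengths
    (My); the root is excluded, and terminal branches are included unless
    ``include_terminal`` is false.  Outliers are branches whose internally
    studentized OLS residual exceeds ``resid_threshold`` in magnitude.
    """
    if lengths is None:
        lengths = rec.tree.branch_lengths()
    internal = set(rec.tree.internal_branch_ids())
    branches = [
        b
        for b in rec.branch_counts
        if b != "ROOT" and (include_terminal or b in internal)
    ]
    missing = [b for b in branches if b not in lengths]
    if missing:
        raise ValueError(f"no length for branches: {missing}")
    if len(branches) < 3:
        raise ValueError("need at least three branches for a regression")
    x = np.array([lengths[b] for b in branches], dtype=float)
    y = np.array([rec.branch_counts[b] for b in branches], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("branch lengths have zero variance")

    if np.ptp(y) == 0:
        # no association is expressible; define r = 0, p = 1
        r, p = 0.0, 1.0
        slope, intercept = 0.0, float(y[0])
        studentized = np.zeros_like(y)
    else:
        r, p = stats.pearsonr(x, y)
        import statsmodels.api as sm

        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        intercept, slope = fit.params
        from statsmodels.stats.outliers_influence import OLSInfluence

        studentized = OLSInfluence(fit).resid_studentized_internal

    outliers = [
        b for b, t in zip(branches, studentized) if abs(t) > resid_threshold
    ]
    table = pd.DataFrame(
        {
            "branch": branches,
            "length_my": x,
            "n_losses": y.astype(int),
            "std_residual": studentized,
            "outlier": [b in outliers for b in branches],
        }
    )
    return BranchRegression(
        table, float(r), float(r) ** 2, float(p), float(slope), float(intercept),
        outliers,
    )


def foreground_from_reconstruction(
    rec: LossReconstruction, internal_only: bool = True
) -> list[str]:
    """Genes with at least one loss on an internal branch (the foreground
    for over-representation analysis); with ``internal_only=False``, genes
    with any loss at all.  Sorted, deduplicated."""
    internal = set(rec.tree.internal_branch_ids())
    out = set()
    for gene, branches in rec.gene_loss_branches.items():
        if not branches:
            continue
        if not internal_only or branches & internal:
            out.add(gene)
    return sorted(out)
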