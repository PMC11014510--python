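"""Parsimony topology tests by per-character resampling.

To ask whether a branch of the most-parsimonious (MP) tree is supported by
the data, the branch is collapsed to a polytomy and the per-gene Dollo
loss counts of the collapsed tree are compared with those of the MP tree.
Two paired tests are reported per comparison:

* **Templeton (winning-sites)** — a two-sided Wilcoxon signed-rank test on
  the nonzero per-gene score differences (normal approximation with tie
  correction; exact sign-flip enumeration when twelve or fewer genes
  differ).
* **RELL** — the observed total score difference is compared against gene
  bootstrap resamples of the per-gene differences, mean-centred across
  replicates (the SH convention, appropriate when the reference tree was
  itself selected as optimal); one-sided, since collapsing a branch can
  never lower a Dollo score.  Add-one smoothing keeps the p-value off an
  exact zero.

An optional joint correction compares each branch's observed difference
against the maximum centred resampled difference across all collapsed
trees (a familywise SH-style scan); the per-branch values are the default
report.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dollo_core import Phylo, collapse_branch, per_gene_losses
from .toga_io import PresenceMatrix

__all__ = [
    "ScoreProfile",
    "TopologyTestResult",
    "score_profile",
    "paired_topology_test",
    "branch_sh_scan",
    "templeton_p",
]

EXACT_MAX_N = 12


@dataclass
class ScoreProfile:
    """Per-gene Dollo loss counts of one matrix on one tree."""

    tree: Phylo
    genes: list[str]
    counts: np.ndarray  # int, ordered as genes

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class TopologyTestResult:
    label: str
    delta: int  # alternative total - reference total
    p_templeton: float
    p_rell: float
    n_resamples: int
    seed: int
    p_rell_joint: float | None = None


def score_profile(tree: Phylo, matrix: PresenceMatrix) -> ScoreProfile:
    counts = per_gene_losses(tree, matrix.states, matrix.species)
    return ScoreProfile(tree, list(matrix.genes), counts.astype(np.int64))


def templeton_p(d: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on score differences.

    Zeros are dropped; ties get average ranks.  Exact enumeration of all
    sign assignments when at most :data:`EXACT_MAX_N` differences remain,
    else the normal approximation with tie correction (no continuity
    correction, matching the plain large-sample Templeton test).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    if n <= EXACT_MAX_N:
        ranks = stats.rankdata(np.abs(d))
        observed = abs(float(np.sum(np.sign(d) * ranks)))
        count = 0
        total = 0
        for signs in itertools.product((-1.0, 1.0), repeat=n):
            s = abs(float(np.dot(signs, ranks)))
            total += 1
            if s >= observed - 1e-9:
                count += 1
        return count / total
    res = stats.wilcoxon(d, alternative="two-sided", correction=False,
                         method="approx")
    return float(res.pvalue)


def _rell_sums(d: np.ndarray, n_resamples: int, rng: np.random.Generator,
               chunk: int = 1000) -> np.ndarray:
    """Bootstrap sums of d over gene resamples, in memory-bounded chunks."""
    n = d.size
    sums = np.empty(n_resamples)
    done = 0
    while done < n_resamples:
        k = min(chunk, n_resamples - done)
        idx = rng.integers(0, n, size=(k, n))
        sums[done : done + k] = d[idx].sum(axis=1)
        done += k
    return sums


def paired_topology_test(
    ref: ScoreProfile,
    alt: ScoreProfile,
    n_resamples: int = 10_000,
    seed: int = 0,
    label: str = "",
) -> TopologyTestResult:
    """Templeton and centred-RELL comparison of two score profiles."""
    if ref.genes != alt.genes:
        raise ValueError("profiles cover different gene lists")
    d = (alt.counts - ref.counts).astype(np.int64)
    delta = int(d.sum())
    p_t = templeton_p(d)
    rng = np.random.default_rng(seed)
    sums = _rell_sums(d.astype(float), n_resamples, rng)
    centred = sums - sums.mean()
    p_r = (1 + int((centred >= delta).sum())) / (n_resamples + 1)
    return TopologyTestResult(label, delta, p_t, p_r, n_resamples, seed)


def branch_sh_scan(
    mp_tree: Phylo,
    matrix: PresenceMatrix,
    n_resamples: int = 10_000,
    seed: int = 0,
    joint: bool = False,
) -> list[TopologyTestResult]:
    """Collapse each internal branch of the MP tree in turn and test it.

    Per branch: the collapsed topology is re-profiled and compared with the
    MP profile; the score difference is >= 0 by the refinement property of
    Dollo scores.  With ``joint=True`` an additional familywise p-value per
    branch is computed against the max-statistic across all collapsed
    alternatives (shared resampling indices).
    """
    internal = mp_tree.internal_branch_ids()
    if not internal:
        raise ValueError("tree has no internal branch to collapse")
    ref = score_profile(mp_tree, matrix)
    seeds = np.random.SeedSequence(seed).spawn(len(internal))
    results = []
    diffs = []
    for bid, ss in zip(internal, seeds):
        alt_tree = collapse_branch(mp_tree, bid)
        alt = score_profile(alt_tree, matrix)
        child_seed = int(ss.generate_state(1)[0] % (2**31 - 1))
        res = paired_topology_test(
            ref, alt, n_resamples=n_resamples, seed=child_seed,
            label=f"collapse:{bid}",
        )
        results.append(res)
        diffs.append((alt.counts - ref.counts).astype(float))

    if joint:
        rng = np.random.default_rng(
            int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
        )
        n = len(matrix.genes)
        centred_max = np.full(n_resamples, -np.inf)
        chunk = 1000
        done = 0
        all_d = np.stack(diffs)  # branches × genes
        while done < n_resamples:
            k = min(chunk, n_resamples - done)
            idx = rng.integers(0, n, size=(k, n))
            sums = all_d[:, idx].sum(axis=2)  # branches × k
            sums = sums - sums.mean(axis=1, keepdims=True)
            centred_max[done : done + k] = sums.max(axis=0)
            done += k
        for res in results:
            res.p_rell_joint = (1 + int((centred_max >= res.delta).sum())) / (
                n_resamples + 1
            )
    return results
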