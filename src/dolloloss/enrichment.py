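"""Hypergeometric over-representation analysis (ORA) of lost genes.

Given a foreground gene set (e.g. genes lost on internal branches), a
background universe (all reference genes) and a GMT collection of
annotation sets, each set is tested for enrichment with the hypergeometric
upper tail: for a set with K background members, foreground size n and
background size N, p = P(X >= k) with X ~ Hypergeom(N, K, n), where k is
the foreground overlap.  The enrichment ratio is (k/n)/(K/N).  Sets are
size-filtered on their background-restricted size K (defaults 10–200, the
regime where a large foreground does not trivially light up huge
categories), p-values are Benjamini–Hochberg adjusted across all tested
sets, and significant terms can be de-redundantized by affinity
propagation on the Jaccard similarity of their memberships.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "OraRow",
    "ApReduction",
    "read_gmt",
    "write_gmt",
    "ora",
    "ora_frame",
    "ap_reduce",
]


@dataclass
class GeneSetCollection:
    """term id -> (description, member gene list); members deduplicated."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self):
        clean = {}
        for term, (desc, members) in self.sets.items():
            seen, uniq = set(), []
            for g in members:
                if g not in seen:
                    seen.add(g)
                    uniq.append(g)
            if not uniq:
                raise ValueError(f"gene set {term!r} is empty")
            clean[term] = (desc, uniq)
        self.sets = clean

    def __len__(self):
        return len(self.sets)

    def terms(self) -> list[str]:
        return list(self.sets)

    def members(self, term: str) -> list[str]:
        return self.sets[term][1]

    def description(self, term: str) -> str:
        return self.sets[term][0]


@dataclass(frozen=True)
class OraRow:
    term: str
    description: str
    k: int  # foreground ∩ set
    K: int  # background ∩ set
    n: int  # foreground size
    N: int  # background size
    ratio: float  # (k/n)/(K/N)
    p: float  # hypergeometric upper tail P(X >= k)
    q: float  # BH-adjusted


@dataclass
class ApReduction:
    exemplars: list[str]
    assignment: dict[str, str]  # every input term -> its exemplar
    converged: bool


def read_gmt(stream) -> GeneSetCollection:
    """Parse GMT text (path, text or lines): term, description, genes...,
    tab-separated; duplicate genes within a set collapse, duplicate term
    ids are an error."""
    if isinstance(stream, (str, Path)):
        p = Path(stream)
        if isinstance(stream, Path) or (len(str(stream)) < 4096 and p.is_file()):
            lines = p.read_text().splitlines()
        else:
            lines = str(stream).splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(
                f"GMT line {lineno}: need term, description and >=1 gene"
            )
        term, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if term in sets:
            raise ValueError(f"GMT line {lineno}: duplicate term id {term!r}")
        if not genes:
            raise ValueError(f"GMT line {lineno}: no genes")
        sets[term] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection) -> str:
    lines = []
    for term, (desc, members) in collection.sets.items():
        lines.append("\t".join([term, desc, *members]))
    return "\n".join(lines) + "\n"


def ora(
    foreground: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 200,
) -> list[OraRow]:
    """Hypergeometric upper-tail test of every size-eligible set.

    Sets are first restricted to the background; sets with background-
    restricted size K outside [min_size, max_size] are skipped.  Rows come
    back sorted by p, with BH q-values computed over all tested sets.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg:
        raise ValueError("empty foreground")
    stray = fg - bg
    if stray:
        raise ValueError(
            f"{len(stray)} foreground genes missing from background, "
            f"e.g. {sorted(stray)[:10]}"
        )
    if min_size > max_size:
        raise ValueError("min_size exceeds max_size")
    N, n = len(bg), len(fg)
    rows = []
    for term, (desc, members) in sets.sets.items():
        restricted = [g for g in members if g in bg]
        K = len(restricted)
        if not (min_size <= K <= max_size):
            continue
        k = sum(1 for g in restricted if g in fg)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N)
        rows.append((term, desc, k, K, p, ratio))
    if not rows:
        return []
    pvals = np.array([r[4] for r in rows])
    q = multipletests(pvals, method="fdr_bh")[1]
    out = [
        OraRow(term, desc, k, K, n, N, ratio, p, float(qi))
        for (term, desc, k, K, p, ratio), qi in zip(rows, q)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def ora_frame(rows: Sequence[OraRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


def _jaccard_matrix(members: list[set]) -> np.ndarray:
    m = len(members)
    S = np.zeros((m, m))
    for i in range(m):
        S[i, i] = 1.0
        for j in range(i + 1, m):
            inter = len(members[i] & members[j])
            union = len(members[i] | members[j])
            S[i, j] = S[j, i] = inter / union if union else 0.0
    return S


def ap_reduce(
    significant: Sequence[OraRow],
    sets: GeneSetCollection,
    damping: float = 0.7,
    max_iter: int = 500,
    background: Iterable[str] | None = None,
) -> ApReduction:
    """Affinity-propagation redundancy reduction of significant terms.

    Similarity is the Jaccard index between set memberships (restricted to
    the background when one is given); preferences are the median
    similarity.  Exemplar terms are returned with every input term mapped
    to its exemplar.  On non-convergence all terms become their own
    exemplars, flagged via ``converged=False``.
    """
    if not significant:
        raise ValueError("no significant rows to reduce")
    if not (0.5 <= damping < 1):
        raise ValueError("damping must be in [0.5, 1)")
    terms = [r.term for r in significant]
    bg = set(background) if background is not None else None
    members = []
    for t in terms:
        m = set(sets.members(t))
        if bg is not None:
            m &= bg
        members.append(m)
    if len(terms) == 1:
        return ApReduction([terms[0]], {terms[0]: terms[0]}, True)

    S = _jaccard_matrix(members)
    pref = float(np.median(S))
    from sklearn.cluster import AffinityPropagation

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sklearn warns itself on non-convergence
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damping,
            max_iter=max_iter,
            preference=pref,
            random_state=0,
        ).fit(S)
    centers = getattr(ap, "cluster_centers_indices_", None)
    if centers is None or len(np.atleast_1d(centers)) == 0 or (
        np.any(np.asarray(ap.labels_) < 0)
    ):
        warnings.warn("affinity propagation did not converge; "
                      "returning all terms as exemplars", stacklevel=2)
        return ApReduction(list(terms), {t: t for t in terms}, False)
    exemplars = [terms[i] for i in centers]
    assignment = {
        terms[i]: terms[centers[lab]] for i, lab in enumerate(ap.labels_)
    }
    return ApReduction(exemplars, assignment, True)
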