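# Methods

## The Dollo model and the loss-counting rule

A gene's presence/absence across species is a binary character on a rooted
tree.  Dollo parsimony allows one gain (0→1) and unlimited irreversible
losses (1→0); the optimal reconstruction minimises the loss count.  The
package's default mode pins the gain to the root: when the character
universe is defined by an outgroup reference genome (every gene in the
matrix existed in the ingroup ancestor), "absent" can only mean "lost".
Under that convention the minimum loss count of a character equals the
number of maximal clades whose observed leaves are all 0 — one loss on
each such clade's stem; siblings containing a 1 forbid any higher
placement.  Unknown states (`?`) resolve in the loss-minimising
direction: an entirely-unknown clade stays present, and unknown leaves
inside an all-0 clade join the loss.  A free-gain mode (gain on the
branch above the MRCA of the 1-leaves) is provided for generality.

Two conventions exist for a character observed 0 in *every* species.  The
public scoring (`tree_score`, `dollo_fit`, `reconstruct_losses`) charges
one loss per root child — such genes are reference-private artifacts and
are additionally reported as a separate list.  The tree search internally
uses a "stem" variant charging a single loss on a virtual root edge,
because only that variant is monotone under taxon restriction (the bound
branch-and-bound prunes with; see below).  On binary trees the two differ
per character by a constant equal to the number of all-0 columns, so the
optima coincide; reported search scores always use the public convention.

Polytomies are scored *hard* (directly on the multifurcating tree), not
as minima over resolutions — matching classic discrete-parsimony program
behaviour and keeping the branch-collapse scan cheap.

Correctness is checked against an exhaustive reference
(`dolloloss.bruteforce`): enumerate all internal-node state assignments
(and `?`-leaf resolutions), keep the admissible single-origin ones, and
take the minimum loss count.

## Tree search

Rooted binary topologies are enumerated by stepwise taxon addition
((2n−3)!! trees).  Branch-and-bound prunes a partial tree when its
restricted stem-convention score already exceeds the incumbent; this is
sound because restricting a character to a leaf subset can only lower its
stem-convention score (any optimal full assignment induces an assignment
on the subtree of no greater cost — a 1→0 edge maps to at most one
induced loss edge, and a 0-state induced root is absorbed by the virtual
root-edge loss).  The initial incumbent comes from greedy stepwise
addition; taxa are added in order of decreasing score impact (the change
in the greedy tree's score when that taxon is removed), which tightens
bounds early.  All co-optimal trees are retained, deduplicated by a
canonical sorted-newick topology key, and the first in canonical order is
the headline tree.  The exact search is limited to 12 taxa by default;
beyond it, random-addition-order stepwise trees are refined by steepest
nearest-neighbour-interchange hill climbing over `n_starts` seeded
restarts.

Branch support: gene columns are resampled with replacement (same column
count), the search is rerun per replicate, and each replicate contributes
its headline tree.  A clade's support is the percentage of replicates
containing it; clades above the threshold (strict majority by default)
are assembled greedily by descending support, with an explicit
compatibility check, into the consensus.

## Topology tests

For a reference (MP) tree and an alternative — in the scan, the MP tree
with one internal branch collapsed — the per-gene loss-count differences
`d_g = l_g(alt) − l_g(ref)` carry all the information.  Collapsing can
only increase a Dollo score, so `Σ d_g ≥ 0`.  Two p-values are reported:

* **Templeton**: two-sided Wilcoxon signed-rank on the nonzero `d_g`.
  Twelve or fewer nonzero differences trigger exact sign-flip enumeration
  with tied (average) ranks; otherwise the normal approximation with tie
  correction (scipy).  The exact path is in-house because scipy's exact
  mode does not handle ties.
* **RELL**: bootstrap the gene indices, sum `d` per replicate, centre the
  replicate sums at their mean (the SH convention — appropriate because
  the reference was itself selected as optimal; the uncentred KH variant
  would be anti-conservative), and report the add-one-smoothed one-sided
  tail `(1 + #{centred ≥ observed}) / (R + 1)`.  Smoothing keeps p off an
  exact zero, so "P < 1/(R+1)" is the strongest attainable statement.

A joint familywise variant (max centred statistic across all collapsed
alternatives, shared resample indices) is available behind a flag; the
per-branch values are the default report since branch-wise support is
what the scan is for.

## Ancestral losses and the branch-rate regression

`reconstruct_losses` aggregates per-gene loss placements (root-present
mode) into per-branch counts and a gene × branch event table; the total
equals `tree_score` exactly, by construction.  `branch_regression`
regresses per-branch counts on branch durations (My): Pearson r with the
two-sided t test `t = r·√((n−2)/(1−r²))`, an OLS fit, and outliers
defined as |internally studentized residual| > 2 (threshold exposed; the
choice of 2 ≈ flagging beyond the 95% band is conventional, not
canonical).  Terminal branches are included by default — assembly-quality
artifacts concentrate there and should be visible — with a switch to
restrict to internal branches.  Zero variance in counts yields r = 0,
p = 1 (no association is expressible; scipy would return NaN); zero
variance in lengths is an error.

## Clustering

Manhattan distance on binary rows counts disagreeing genes and equals the
squared Euclidean distance of those rows — which is why the
Kaufman–Rousseeuw relational criterion
`Σ_k (Σ_ij u_ik^m u_jk^m d_ij) / (2 Σ_j u_jk^m)` can be minimised with
the Hathaway–Bezdek relational fuzzy c-means update (exact fuzzy c-means
in the embedded space).  For distance matrices with no Euclidean
embedding the update can overshoot; the iteration therefore monitors the
objective and stops (keeping the last descending state) on any increase.
The fuzzifier default is m = 1.2: m → 1 collapses memberships to hard
assignment and makes the update degenerate, so a genuinely fuzzy but
conservative value is used; m is a parameter.

Ordination is classical (Torgerson) MDS — double-centre −d²/2,
eigendecompose, keep the top requested positive axes — chosen over
stress-minimising MDS because it is deterministic and exact on
Euclidean-embeddable input, which makes it testable to 1e-8; the
non-metric variant is a non-goal.  Hard partitions come from
scikit-learn k-means (10 seeded restarts, best inertia).  Diagnostics
report per-K within-cluster dispersion (elbow heuristic) and the adjusted
Rand index between successive-K partitions, a scalar stand-in for a
cluster-stability tree: low ARI between K and K−1 marks the arrival of an
unstable split.

## Over-representation analysis

Hypergeometric upper tail `P(X ≥ k)` with `X ~ Hypergeom(N, K, n)` via
scipy's log-space implementation (verified against exact rational
arithmetic to 1e-12 for N ≤ 200).  Sets are restricted to the background
before the size filter, which applies to the background-restricted size K
(defaults 10–200 — the explicit parameter choice; with a foreground
covering a few percent of the genome, very small and very large
categories are the false-positive-prone extremes).  The family blacklist
is applied to foreground *and* background before testing so N reflects
the tested universe.  BH q-values are computed over all tested sets; the
default reporting filter is q ≤ 0.10.  Redundancy reduction runs
scikit-learn affinity propagation on the Jaccard similarity of set
memberships with the median similarity as preference — the technique's
usual self-tuning default; similarity and preference are package choices
since only the technique itself is canonical.

## The simulator and what passing tests mean

`simulate_losses` implements the generative counterpart of the Dollo
assumption: every gene present at the root; on each branch *b*, a gene
still present at the parent is lost with probability
`1 − exp(−λ · m_b · t_b)` (base rate λ per gene per My, branch multiplier
m_b, length t_b); loss is terminal within the subtree.  Parallel losses
in disjoint subtrees arise naturally and are what makes reconstruction
non-trivial (parsimony merges some of them, hence inferred ≤ true
losses, with equality for single-loss genes).

Fixture conditions (chosen once, as plausible study-scale conditions):

* **17-taxon tree** — the packaged Atlantogenata-shaped topology with
  synthetic but plausibly scaled divergence times (root at 96 My);
  filename and docstring mark it synthetic.
* **Base rate 8e-4 /gene/My, 2,000 genes** — yields per-species loss
  fractions of a few percent, the order genome-wide ortholog screens
  report, while keeping 100-replicate batteries fast.
* **Burst fixture** — 5× multiplier on the Afrotheria stem; detection is
  measured over 100 seeded replicates.
* **Topology-recovery fixture** — a 7-leaf tree (10 My branches, 20 My
  for the odd leaf), rate 5e-3, 400 genes; replicates qualify when every
  internal branch carries ≥ 5 exclusive losses, and recovery requires the
  generating topology to be the unique optimum.
* **Clade fixture** — four disjoint clades covering all 17 species, each
  stem's multiplier calibrated for ~35% stem loss probability over a
  3e-4 base rate: a strong block of shared derived losses per clade.
* **Enrichment fixture** — designated sets over-sample burst-branch
  losses at 8× the background fraction, set sizes 30–60, 3 designated of
  40; ORA null calibration draws random foregrounds of the pipeline's own
  foreground size from the simulated universe, a regime where the
  discrete hypergeometric tail is fine-grained enough for the nominal
  level to be nearly attainable.

The simulator emulates irreversible loss with branch-rate heterogeneity
and category-enriched losses.  It does **not** emulate ortholog-caller
error (false loss calls from assembly gaps), gene gain/duplication,
correlated loss across genes, or drifting status vocabularies beyond an
optional relabelling noise mode — so passing tests demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to systematic misclassification in real alignments.

## Numerical and interface choices

* Branch identifiers are stable child-node-keyed strings (leaf label,
  internal node label, or the sorted `|`-joined clade leaf set), so loss
  maps survive re-serialisation.
* Duplicate gene rows in loss summaries resolve by "any loss ⇒ 0" with a
  warning; coding is total.
* Union gene universes fill species-absent genes with state 1 (the
  likely-present collapse); intersection and explicit-reference-list
  policies are available.
* PHYLIP export uses the classic 10-character name field with explicit
  collision detection; NEXUS export carries gene names in CHARLABELS and
  round-trips exactly.
* Bootstrap and search tie-breaks are deterministic (canonical topology
  sort); all stochastic routines take explicit seeds and are reproducible
  bit-for-bit.

## Known limitations

* The exact search cost grows as (2n−3)!!; beyond ~12 taxa only the
  heuristic is practical, and NNI hill climbing carries no optimality
  guarantee.
* Dollo parsimony underestimates loss counts when parallel losses occur
  in sister lineages (merged onto the stem); rate heterogeneity is
  detected post hoc by the regression, not modelled.
* The fuzzy-clustering descent guarantee holds for Euclidean-embeddable
  distances (Manhattan-on-binary qualifies); other metrics fall back to
  the monitored-stop behaviour.
* Likelihood or Bayesian gene-content models, non-metric MDS, and GSEA-
  style rank enrichment are out of scope.
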