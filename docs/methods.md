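# Methods

## The annotation model

`pia` treats annotation as a placement problem. For a gene family we hold
fixed a curated reference: an alignment of family members, an unrooted
tree over those members with branch lengths in expected substitutions per
site, and a tier label on functionally characterized tips (LANDMARK1 =
the sought function, LANDMARK2 = characterized relatives with a different
function). A query is annotated by where it attaches to this tree, not by
which single sequence it most resembles — which matters precisely when
the closest sequence is a paralog.

The assumptions are those of standard probabilistic phylogenetics: sites
evolve independently under a reversible continuous-time Markov chain on
the 20 amino acids; the reference topology and branch lengths are treated
as known; queries are single sequences placed independently of each other
(no interaction between simultaneous queries).

## Substitution model

The default and only built-in model is WAG: exchangeabilities `s_ij` and
stationary frequencies `π` as published, with `Q_ij = s_ij π_j`, rows
summing to zero, rescaled so `−Σ π_i Q_ii = 1` (branch lengths are then
expected substitutions per site). `P(t) = exp(Qt)` is computed through
the symmetric eigendecomposition of `diag(√π) Q diag(1/√π)`, exact for
reversible models. Two optional departures exist and default off, since
the reference trees this package targets are fit under plain WAG:
empirical (+F) frequencies taken from the reference alignment, and
discrete-gamma rate variation (`n_gamma_cats` > 1, category means
computed from exact gamma partial expectations, mean rate 1). Gaps and
`X` in alignment rows are missing data (all-ones partials); other
non-residue characters are errors.

## Likelihoods and branch-length optimization

`pruning_loglik` is Felsenstein pruning with per-node, per-site
rescaling; its value is independent of the virtual root (pulley
principle), which the tests verify to < 1e-9 on every edge of random
trees, and it agrees with explicit summation over all ancestral-state
assignments to < 1e-8 on small trees. Single-branch optimization is
bounded derivative-free scalar maximization on [1e-8, 10]
substitutions/site with tolerance 1e-6; a branch is updated only when
the refit does not lose likelihood, so every optimization trace is
monotone. Whole-tree refreshes (`reoptimize_branch_lengths`) sweep all
edges up to `sweeps` times (default 3) and stop when a sweep gains
< 1e-4 log-units.

## Placement

For each edge, the query is attached by a new node splitting the edge:
three subtrees hang from the attachment point — the part of the tree
below the edge's child end, the rest of the tree seen from the parent
end, and the query on its pendant branch. Conditional likelihoods for
the first two are precomputed once per (tree, alignment): "down"
partials by postorder and "up" partials by preorder, both rescaled
per site. Scoring an edge then costs three 20×20 transition matrices
and one per-site product, so a full placement sweep never re-runs
full-tree pruning; the tests confirm equality with a from-scratch
pruning on the physically rebuilt query-attached tree.

Per edge, pendant length (bounds [1e-8, 10], start 0.1) and attachment
position (bounds [0, edge length], start midpoint) are optimized
coordinate-wise, at most 32 rounds, tolerance 1e-6; the original edge's
two sub-lengths are constrained to sum to its length and no other branch
moves — the reference is never re-estimated. All edges are reported,
ranked by log-likelihood with likelihood-weight ratios (softmax over
edges); near-ties (< 1e-9) are ordered by smaller edge id for
determinism. Output is jplace v3 against the `{N}`-edge-numbered Newick.

## Homology screen

Candidate ORFs come from six-frame translation: every maximal stop-free
stretch ≥ `min_orf_aa` (default 30) residues, with no start-codon
requirement and edge-truncated stretches included, since assembled
transcript fragments routinely cut into coding sequence. Candidates are
scored against family baits by optimal Smith–Waterman local alignment
with affine gaps (BLOSUM62, open −11, extend −1, where "open" is the
cost of the first gap residue); E-values use the Karlin–Altschul formula
with the standard gapped constants λ = 0.267, K = 0.041 and the family's
total bait length as the database size, since each family is searched
separately. A candidate's family E-value is its best bait E-value;
candidates above the cutoff (default 1e-20) are discarded and the
`top_k` (default 3) smallest E-values are retained, ties broken by raw
score then query id so retention is input-order invariant. The top-k is
applied over ORFs; per-bait hits remain available in the hit log.
Externally produced BLAST outfmt-6 tables can be imported instead of
the built-in search.

## Profile alignment

Queries are added to the reference alignment one at a time by
profile-to-sequence dynamic programming: the match score of query
residue `q` against column `c` is `occ(c) · Σ_a f_c(a) S(a, q)` with
`f_c` the column's residue frequencies over non-gap rows, `occ(c)` its
non-gap fraction and `S` the search substitution matrix; gap penalties
as in the search. The alignment is global in the query and semi-global
in the profile (terminal deletions free — ORFs are fragments). Query
residues aligning to no column become new all-gap insert columns
(lower-case in output, a2m-style) and are dropped again by
`mask_query_to_ref` before placement, which guarantees the invariant the
tree depends on: removing the query row and all-gap columns reproduces
the reference alignment byte-for-byte. When two gappings score equally
(e.g. two columns with identical profiles) the reported path is an
arbitrary optimum; the immutability invariant holds regardless.

## Landmark classification

The flag attached to each query is an explicit stand-in for reading the
tree by eye, and is labelled advisory: `candidate_ortholog_context` when
the nearest landmark by patristic distance from the attachment point is
LANDMARK1 **and** the pendant branch is ≤ `pendant_max` (default twice
the median terminal branch length of the reference tree — "short branch"
must be judged relative to the tree's own scale);
`distant_relative_context` when the nearest landmark is LANDMARK2;
`ambiguous` otherwise, including tier ties within 1e-9 and trees with no
landmarks. Both tier distances are always reported so the call can be
audited. The presence matrix marks (family, sample) cells with ≥ 1
candidate record; contamination marks ("C") are user judgements passed
through, never computed.

## Reference-package construction

Dereplication is greedy longest-first: at identity 1.0 exact duplicates
and exact substrings collapse onto the longest representative (ties by
id); below 1.0 the criterion is best ungapped sliding-offset identity
over the shorter length. Long-branch pruning iteratively removes the
longest terminal branch exceeding `factor` × the current median terminal
length (default factor 10), recomputing the median after each removal,
never below 3 tips, with every removal logged. Both rules are this
package's own explicit formulations of common curation practice; their
thresholds are exposed. Topology search and bootstrap are out of scope
by design — topologies come from external tree software and only branch
lengths are refreshed here. Package directories carry MD5 checksums in
the manifest and are validated (tree tips == alignment rows, resolvable
landmarks) on every read.

## Simulator and what passing tests mean

The simulator evolves gap-free protein alignments along random
bifurcating trees (sequential random edge attachment; branch lengths
exponential with mean 0.1 substitutions/site) by drawing root states
from π and propagating through `P(t)`; queries with known truth evolve
from an edge midpoint for a chosen pendant length. Everything is a pure
function of one integer seed.

Simulated data lacks indels, fragmentary ORFs, composition bias and
misassembly, so green tests demonstrate correctness of the algorithms
under the model, not performance on real transcriptomes. Insert-column
handling is exercised with hand-built gapped fragments instead.

Experiment sizes used by the test suite and the acceptance script, and
the reasoning behind them:

- Likelihood-oracle equality uses trees of ≤ 4 tips and ≤ 5 sites because
  the oracle enumerates 20^internal-nodes states per site.
- Exact-equality checks between the cached-partial placement and full
  re-pruning use 6 tips × 60 sites, keeping |logL| small enough that an
  absolute 1e-8 tolerance is meaningful in double precision (at |logL|
  ≈ 10³ accumulation noise alone reaches ~3e-8).
- Placement recovery runs 50 queries at 16 tips × 200 sites, pendant 0.1.
  Accuracy at these conditions varies by tree: under Exp(0.1) branch
  lengths some trees contain several near-zero internal edges among
  which 200 sites carry almost no discriminating signal, and per-edge
  likelihoods there are grid-verified optimal — misses are information
  limits, not optimizer failures.
- Branch-length recovery (30% relative error at 2000 sites) uses a fixed
  6-tip tree with lengths in [0.08, 0.30]: relative error is ill-posed
  for near-zero branches, where a handful of expected substitutions
  bounds the achievable precision.
- The end-to-end run plants a query next to a LANDMARK1 tip with pendant
  min(0.05, half the tree's median terminal length), i.e. comfortably
  inside the classifier's own short-branch ceiling — the experiment
  verifies pipeline wiring, so the planted sequence must be one the
  stated rule classifies as a candidate.

## Known limitations

- Search is full dynamic programming without heuristic seeding: suitable
  for desk-scale transcriptomes against per-family bait sets, not for
  genome-scale all-vs-all screens.
- E-value constants are the standard gapped blastp values, not refit to
  the chosen matrix/gap combination.
- One-by-one query insertion means simultaneous queries do not inform
  each other's alignment or placement.
- The orthology flag is a heuristic over patristic distances; it cannot
  outperform the curation of the landmark table it is given.
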