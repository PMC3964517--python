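# Methods

## The model

`powergraph` losslessly compresses a network into a *power graph*: a set
of poweredges, each connecting two power nodes A and B (sets of ordinary
nodes) and asserting that every node in A is connected to every node in B,
plus a remainder list of edges covered by no poweredge.  Power nodes may
overlap arbitrarily — a node can sit in one or both sides of one or many
components — which is what distinguishes this decomposition from
partition-based community detection and from hierarchies of nested power
nodes.

Costs are counted in an identifier code: any node or power node costs
log2(N) bits, where N is the number of nodes of the graph being
compressed.  The number of power nodes is bounded by N, so log2(N) also
bounds the per-power-node cost; we always charge the bound, which makes a
component's gain independent of how many other components are selected.
A raw edge costs two identifiers.  A poweredge costs one identifier per
member node plus two for the power nodes themselves, so the gain of
encoding the complete biclique (A, B) as a poweredge is

    delta_i = [2 e(A, B) - n_A - n_B - 2] * log2(N)

with e(A, B) the number of distinct edges asserted:

| mode                | e(A, B)                              |
|---------------------|--------------------------------------|
| directed, bipartite | n_A n_B                              |
| directed, no loops  | n_A n_B - n_AB                       |
| undirected + loops  | n_A n_B - n_AB (n_AB - 1) / 2        |
| undirected, no loops| n_A n_B - n_AB (n_AB + 1) / 2        |

where n_AB = |A ∩ B|; the undirected corrections remove double-counted
unordered pairs inside the overlap (and the overlap's self-pairs when
loops are disallowed).  The directed no-loop row is our symmetric
extension of the undirected convention: the source formulation defines
the overlap correction only for undirected graphs, so a directed
component with A ∩ B ≠ ∅ excludes the diagonal unless the input itself
contains self-loops.

When several components are selected, an edge covered more than once
saves its raw cost only once.  The total gain is therefore computed from
first principles —

    delta_i_total = 2 |E| log2 N - [ sum_k (n_A^k + n_B^k + 2) log2 N + 2 |R| log2 N ]

with R the uncovered remainder — rather than through the equivalent
"sum of per-component gains minus 2 log2 N per repeated coverage"
shortcut; the shortcut is verified as an identity in the test suite.
Because every cost is an integer multiple of log2(N) computed in exact
integer arithmetic, cost identities hold to the last bit of the float and
ties in the greedy selection are exact, never epsilon-dependent.

The decomposition bookkeeping follows the identity m = c + r - v per node
pair (adjacency indicator, coverage count, remainder indicator, overlap
count v = max(c - 1, 0)), stored sparsely: only pairs that carry an edge
can have nonzero entries.  `reconstruct` unions the component-asserted
pairs with R and must reproduce the input edge set exactly; this is
asserted property-style over random graphs and random valid selections.

## Candidate enumeration

A-sets are grown along the graph's stable node order (input order): every
node pair sharing >= 2 neighbors is stored; each stored set is extended
with single nodes further on in the iteration sequence while the common
neighborhood keeps >= 2 members; each stored A is emitted as (A, B) with
B its entire common neighborhood.  Common neighborhoods shrink as A
grows, so this apriori-style scheme enumerates exactly the A-sets with
|B| >= 2, each once.  In directed graphs both orientations are grown
(common out-neighbors give A -> B, common in-neighbors give B -> A); in
bipartite graphs only same-part pairs survive seeding.  Duplicate (A, B)
pairs are removed after canonicalisation (in undirected modes the
lexicographically smaller set is stored first).

Pair-seeded growth cannot produce a component whose A side is a single
node, yet a hub with k >= 4 leaves is compressible (gain (k - 3) log2 N).
`include_stars` (default on) therefore also seeds ({v}, neighbors(v)) for
every node of degree >= 4; switching it off reproduces the strict
pair-seeded enumeration.  Enumeration cost grows steeply with density
(roughly N^3 for sparse graphs, N^5 at fixed density), so `max_a_size`
and a candidate cap (default 10^6, with a logged warning on truncation)
keep dense inputs bounded.

## Greedy selection

The first pick maximises the per-component gain; every later pick
maximises the joint total, which reduces to the exact marginal

    [2 |edges(c) \ covered| - n_A - n_B - 2] * log2 N.

Marginals are recomputed against the current covered-edge set each round
(no stale caching).  Selection stops when the best marginal improvement
does not exceed 1e-9 bits; since marginals are integer multiples of
log2 N, this tolerance only separates "zero" from "at least one
identifier" and no behaviour hinges on its exact value.  Ties (exact, by
integer coefficient) prefer the candidate covering more not-yet-covered
edges, then the lexicographically smallest (A, B) — a deterministic rule;
two runs on the same input are bit-identical.

## Term enrichment

A term carried by n_i of the N nodes appears k times in an s-node power
node with hypergeometric probability C(n_i, k) C(N-n_i, s-k) / C(N, s).
The p-value of an observed k* sums the probabilities of all counts *as
likely or less likely* than k*.  This two-sided definition is
tie-sensitive, so probabilities are compared as exact integers (shared
denominator C(N, s)) and converted to float only at the end.  Each tested
term's p-value is Bonferroni-multiplied by T, the number of distinct
terms in the attribute table (the number of hypotheses per power node),
capped at 1.  Both sides of every component are tested and reported
separately.  When the independence assumption behind Bonferroni is
doubtful, `randomized_corrected_pvalue` rewires the node-term membership
network by double-edge swaps preserving node and term degrees and reports
the add-one-smoothed empirical tail probability (1 + exceedances) /
(1 + replicates).

## Null models

`degree_preserving_randomize` applies double-edge swaps: undirected
{a,b},{c,d} -> {a,d},{c,b}; directed (a->b),(c->d) -> (a->d),(c->b),
preserving in- and out-degree jointly (the stricter reading of "same
degree distributions"); bipartite swaps use the directed rule on
left->right edges and cannot cross parts.  Self-loops are left in place
and never created: in edge-set semantics moving a loop would change its
node's neighbor degree.  The default budget is 10 x |edges| successful
swaps with a 100x attempt allowance; mixing convergence is not checked
(standard practice for this null).  A graph admitting no legal swap (e.g.
a triangle) is returned unchanged with a warning.

The compressibility curve records the total gain after each accepted
component.  `null_comparison` runs the full pipeline on the real graph
and on each replicate (replicate seeds drawn deterministically from the
master seed) and summarises per component count: null mean, SD, and the
real curve's z-score, padding shorter curves with their final value
because greedy stops at different depths.  An SD below 1e-9 of the mean's
magnitude is treated as a degenerate (all-identical) null and reported as
z = 0 to avoid manufacturing significance from float-summation noise.

## Synthetic generators

The planted generator embeds known complete bicliques — optionally
sharing nodes between consecutive components, exercising overlapping
power nodes — plus Bernoulli(noise_p) noise on non-planted pairs only, so
ground truth stays exactly recoverable.  Its default conditions (used by
the recovery experiment): 40 nodes, 3 node-disjoint components with sides
drawn uniformly from 3..6, noise_p = 0.05, undirected without loops — a
small sparse regime comparable to the packaged social-network benchmark,
where exact recovery is expected but not trivial (~35 noise edges against
~50 planted).  The bipartite block generator emulates a recipe-ingredient
network: left nodes carry their block as a term, and edges appear with
`within_p` inside blocks and `between_p` across.  What these generators
do not emulate: heavy-tailed degree distributions, correlated noise, or
partially eroded bicliques — so passing recovery tests demonstrates
correctness of the search and selection machinery, not performance on
noisy real data where components may be only approximately complete
(edge exceptions are an explicit non-goal).

The Zachary karate club (34 members, 78 ties) is vendored as a
plain-text fixture with the standard post-split faction labels
(instructor = node 1, president = node 34, 17 members each) and checked
against the independently distributed copy in networkx.

## Problem sizes used in the shipped experiments

Karate compression and enrichment run at full size.  The null comparison
uses 100 replicates in the reproduction script and 20 in the test suite;
the planted-recovery experiment uses 20 seeds; exact-arithmetic
enrichment agreement is exhaustive for N <= 26 in tests (N <= 16 in the
unit suite) and strided up to N = 60 — chosen so the whole suite and the
reproduction script each finish in well under their intended runtimes on
one CPU.

## Known limitations

- Completeness is strict: one missing edge excludes a biclique entirely.
- Greedy selection approximates the NP-hard optimal component subset; no
  optimality gap is tracked.
- The corrected p-values on the club benchmark (President 1.32E-02,
  Instructor 1.45E-02) are convention-sensitive: tiny differences in
  greedy boundaries or in two-sided tie handling shift them, which is why
  the published figures for this analysis (1.43E-02, 2.79E-03) agree in
  significance but not digit-for-digit.
- Weighted networks, multigraphs and within-poweredge exceptions are out
  of scope.
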