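# Methods

## Graph construction

A model is a species × reactions stoichiometric matrix **S** (signed
coefficients), a parallel regulatory matrix **R** with entries in
{−1, 0, +1}, per-reaction reversibility flags and optional canonical group
labels. The reaction-centric digraph has an edge i → j when some species m
is *producible* by i and either *consumable* by j (substrate–product) or a
nonzero regulator of j in **R** (allosteric). An irreversible reaction
produces its positive-coefficient species and consumes its
negative-coefficient ones; a reversible reaction is treated as able to both
produce and consume every species it touches — the maximal-edge reading of
"considered in both directions", applied uniformly. Consequences we accept
deliberately:

- regulatory sign is annotation only; activation and inhibition create the
  same edge, since only topology enters the metric;
- parallel edges from several shared metabolites collapse to one unweighted
  edge (mediators are retained as provenance); edges are unweighted
  throughout — flux-weighted variants are out of scope;
- self-edges (a reaction producing its own substrate or effector) are
  discarded: the round-trip distance of a vertex to itself is zero by
  definition, and a self-loop would otherwise make it 1.

Model variants are produced by deleting species rows (e.g. the cofactors
ATP/NADH/NADPH, which removes every edge they mediate) or zeroing **R**.
A reversible reaction that is itself allosterically regulated receives a
single incoming regulatory edge: the vertex is the reaction, not one of its
directions.

## ShReD and the modularity matrix

Directed all-pairs shortest paths are computed with Floyd–Warshall on unit
edge weights (scipy's csgraph implementation); the ShReD matrix is
S = d + dᵀ. Infinity is IEEE `inf`, whose saturating arithmetic keeps
unreachable pairs infinite through every subsequent sum — never a large
finite surrogate, which would corrupt averages. Finite off-diagonal
ShReDs are ≥ 2 (no self-edges), and finiteness coincides exactly with
shared strong connectivity, which the tests assert against an independent
SCC computation.

Expected round trips use per-vertex averages of finite non-zero ShReDs:
avg_i = Σ_k S_ik / D_i over finite non-zero entries, P_ij = (avg_i +
avg_j)/2, and G_ij = P_ij − S_ij on finite off-diagonal entries, zero
elsewhere. Two conventions are fixed by the worked example rather than by
prose: the sign of G (expected minus actual, so that shorter-than-expected
round trips score positive and attract grouping), and the absence of any
1/n normalization in Q (the full ordered double sum reproduces the example's
Q = 43.2; an unordered sum would halve it). Vertices with no finite
partner get avg = 0; their G rows are zero by the infinity rule regardless.

## Partitioning

Q(s) = sᵀGs is maximized approximately by the leading eigenvector of G:
entries > 0 map to +1, all others (zeros included) to −1. Acceptance
requires Q > ε (ε = 1e−9, a float-noise guard), both signs present, and —
for the ShReD metrics — a directed cycle in each daughter, tested by
iterative removal of zero-in-degree vertices. The recursion separates
weakly connected components first (red tree edges), then attempts the
spectral split (black edges); ShReD and G are recomputed on every induced
subnetwork, because removing vertices changes shortest paths — inherited
parent matrices would be wrong.

Numerical choices:

- eigenvector sign: both orientations give the same Q, but exact-zero
  entries always land on the −1 side, so the orientation decides which side
  they join; we canonicalize the first above-tolerance entry to be
  negative, which reproduces the worked example's published split (the
  zero-entry pair joins the first triangle's side) and makes every run
  deterministic. Entries with |v| ≤ 1e−12 count as zero.
- degenerate leading eigenvalues: every eigenvector within 1e−8 (relative)
  of the top eigenvalue is scored and the best Q kept, first-in-canonical-
  order winning ties.
- side labels: the side containing the smallest vertex id is reported
  first; module ids are preorder integers, stable across runs.

The one-shot eigenvector sign pattern is a heuristic, not an optimizer: on
the worked example it attains the exhaustive 2⁸ maximum, but on small
random cyclic digraphs it can fall short of the exhaustive optimum by
substantially more than a few percent, and no refinement pass (e.g.
Kernighan–Lin-style moves) is applied — multi-way splits and refinement
are deliberately out of scope. The Newman baseline mode uses B = A − kkᵀ/2m
on the undirected simple graph with Newman's original acceptance criteria
(Q > 0, mixed signs) and no cycle requirement, since the cycle test is the
ShReD algorithm's addition.

## Module annotations

Per node: reaction count; number of unique simple directed cycles by
Johnson's enumeration, aborted at 1,000 (cycle counting is
output-sensitive and can be exponential; counts at the cap are flagged);
homogeneity = largest canonical-group fraction (unlabeled reactions form an
implicit NA group); mean ShReD and the count of finite unordered pairs on
the node's induced subnetwork; depth and height counted in black edges only
(component formation is not a partition decision). The mean ShReD of a
cycle-free module is null, not zero, to avoid dragging averages down.

## Local-retroactivity ablation

Setting every ShReD > 2 to infinity *before* computing P and G restricts
retroactivity to reversible-reaction pairs and opposed irreversible pairs.
On the worked example exactly one finite pair survives, G vanishes, and no
split is ever accepted — the ablation that motivates multi-step
retroactivity. The filter is idempotent and never creates finite entries.

## Synthetic data

`example_network()` reconstructs the 8-reaction worked example. Its wiring
is a reconstruction: the printed scalars pin down the two triangles, the
hexagon closure and the 2-cycle, but not where the one-way bridge into
{R7, R8} attaches. We place it at R6 → R7 and verify programmatically that
every cross-side placement is fully equivalent (scalars and final modules)
while same-side placements preserve the scalars but merge two terminal
modules — the fixture therefore claims printed-value equivalence, not
figure fidelity. Construction re-derives every closed-form value and fails
loudly on drift. `toy_stoichiometric_model()` is a species-level model (11
metabolites, 8 irreversible reactions, one feedback inhibition) whose built
graph is exactly the example network, exercising the stoichiometry →
graph pathway. `random_cyclic_network(n, p, seed)` draws directed
Erdős–Rényi graphs, resampling until a directed cycle exists; it is fully
seeded and records its provenance. These generators emulate topology only:
no mass balance, no realistic degree distribution, no hub metabolites. A
pass on them validates the algorithmic machinery, not biological
conclusions about any particular network.

## Problem sizes

Tests run the worked example exhaustively (2⁸ sign vectors), compare
Floyd–Warshall with per-source BFS on 100 random digraphs of up to 50
vertices, check strong-connectivity equivalence on 40 more, and exercise
the spectral-vs-exhaustive comparison on graphs of 4–12 vertices, where
2ⁿ enumeration is exact. Larger inputs (hundreds to a few thousand
reactions) are within the algorithm's reach — Floyd–Warshall is O(n³) and
each recursion level reuses only induced subnetworks — but carry no closed
forms and are left to users' models.

## Known limitations

- Unweighted edges: all reactions are assumed equally engaged; flux-aware
  weighting is future work.
- The spectral split is a heuristic without an approximation guarantee
  (see above); accepted splits are locally good, not certified optimal.
- SBML support covers the core subset (species, reactions, reversibility,
  stoichiometry, modifiers); modifiers carry no sign in core SBML and are
  recorded as +1, which cannot affect topology.
- Cycle counts at the cap are lower bounds; comparisons between
  capped modules are not meaningful.
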