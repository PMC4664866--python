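# Methods

## Model and procedure

`netmend` treats missing-link prediction on an undirected simple graph
G(V, E) as a ranking problem over the candidate universe of all
C(N,2) − M non-adjacent pairs of the training graph (probe links and true
non-links alike; nodes isolated by the split stay in the universe). Two
local similarity indices are provided — common neighbours (CN) and resource
allocation (RA) — and are used raw: ranking needs only the order, so no
normalisation is applied.

The community-based variants (CBCN, CBRA) proceed in four steps:

1. **Partition the training graph** by maximizing Newman modularity
   Q = Σ_r (e_rr − a_r²).
2. **Classify** every candidate pair as intra-community (same label) or
   inter-community.
3. **Rank** each class separately by similarity, descending; ties break
   lexicographically on the node identifiers so every ranking is
   deterministic.
4. **β-interleave** the two lists: draw the head of the intra list with
   probability β, else the head of the inter list; drain whichever list
   remains when the other empties. The merged list preserves both source
   orders, and β ∈ {0, 1} is deterministic regardless of seed.

Intra-community candidates sit in dense neighbourhoods and are easy for
local indices; inter-community candidates form few triangles and are
systematically under-ranked. β trades pure accuracy (β → 1) against
recovering the high-betweenness shortcuts (β → 0).

## Community detection

The default detector is a recursive-bipartition extremal-optimization (EO)
search. Starting from the connected components, each community C is
repeatedly bisected: from a random balanced split, the per-degree
modularity contribution λ_i = κ_i/(2M k_i) − K_{g(i)}/(2M)² (κ_i = links
of i inside its side, K_g = degree sum of the side) defines node fitness;
nodes are ranked worst-first and the rank-r node is relocated with
probability ∝ r^(−τ), τ = 1 + 1/ln n. The best split seen is tracked and a
bisection attempt stops after n² consecutive non-improving relocations; a
split is committed only if it strictly increases global Q, and recursion
continues while splits help. Both hyperparameters are configurable. On the
bundled karate network the detector reaches Q = 0.4188 with 4 communities,
and on all small random graphs in the test suite it attains the exhaustive
enumeration optimum.

The detector is pluggable: downstream code depends only on the
(graph, seed) → Partition contract, so any modularity maximizer can be
substituted. Agreement between partitions is scored as the fraction of
nodes matched under a maximum-weight bipartite matching of community labels
(Hungarian algorithm on the confusion table), which makes the score
invariant to label permutations and to unequal community counts.

## Splits and evaluation

Edges are split uniformly at random into E_T (train), optional E_L (learn)
and E_P (probe); probe and learn sizes are the rounded targets and the
train set takes the remainder. AUC is computed exhaustively over all
probe × nonexistent comparisons, (n′ + 0.5 n″)/n with ties counted at half
weight — the infinite-sample limit of the usual sampled estimator, which is
also available behind a `sample_n` flag. "Nonexistent" means candidate
pairs that are in none of the known edge sets of the experiment at hand;
during learning the probe is by construction unknown, so probe pairs count
as nonexistent there. For pure (single-score) rankings ties are genuine
score ties; interleaved lists define a strict order, so their AUC uses
positions.

⟨B⟩, the mean edge betweenness of the predicted links, is computed by
inserting **all** L predicted links at once and averaging the betweenness
of just those links. All betweenness quantities use the ordered-pair
convention (each unordered source–target pair counted in both directions);
this is the convention under which the karate club's maximum node
betweenness is 462.

## Learning β

`beta_curve` traces mean AUC and ⟨B⟩ over a β grid (default 101 evenly
spaced points; the replicate count defaults to 10). One design choice is
deliberate: the community partition is detected **once per curve** (seeded)
and replicates vary only the interleaving draws. Consequently the β = 0 and
β = 1 grid points have zero variance, and detection stochasticity is
averaged at the level above — across splits/seeds in the recovery tests and
the reconstruction protocol — where it belongs, since a curve describes one
fixed training graph.

β̂\* is the grid point whose ⟨B⟩ is nearest the target (exact equality
cannot hold on a stochastic curve); ties break toward larger β, i.e. higher
accuracy. The constrained variant enforces an AUC floor of
(1 − sacrifice) · AUC_o, with sacrifice = 0.1 by default and AUC_o the
plain CN/RA AUC recomputed on the same train/learn split: if the matching β
already satisfies the floor it is returned unchanged, otherwise β is raised
to the grid point (at or above the matching β) whose AUC is nearest the
floor. The constraint can only raise β, never lower it. The learning path
never touches E_P; the tests corrupt the probe field of a split and verify
the learned values are unchanged.

## Reconstruction protocol

Per replicate: split 80/10/10, learn the constrained β̂\* from E_T vs E_L,
merge E_T ∪ E_L into the observed graph, detect one partition on it (shared
across variants — a paired design that removes detection variance from the
comparison), rank candidates, and add the top L = |E_P| links. Variants:
A₁ (β = 0), A\* (constrained β̂\*), A₂ (β = 1), A₃ (plain CN/RA). Every
reconstructed network therefore has exactly |E| edges. Indices are averaged
over replicates; A₀ is the input network itself.

The six indices: average shortest path over connected pairs only (so the
index stays defined when a reconstruction is disconnected — documented in
the output rather than silently NaN); mean local clustering with degree<2
nodes contributing 0; degree assortativity, reported as undefined (None)
for regular graphs instead of a silent 0; congestibility = maximum node
betweenness; synchronizability = λ_max/λ_2 of the combinatorial Laplacian
of the largest component (≥ 1, equal to 1 exactly for complete graphs);
and SIR spreading ability.

## Synthetic benchmark

The GN planted-partition generator places n = 128 nodes in 4 equal blocks;
intra-block pairs connect with p_in = k_in/(n/4 − 1), inter-block pairs
with p_out = (k_total − k_in)/(n − n/4), giving expected intra/inter
degrees k_in and k_out with k_in + k_out = k_total = 16 by default.
Bernoulli placement (an expected-degree model) is used rather than
exact-degree rewiring; realised degrees therefore fluctuate binomially,
which the generator tests check against 3-standard-error bands. The
benchmark emulates the one property under study — tunable community
strength — and none of the degree heterogeneity, clustering or weighted
structure of real networks, so passing trends on it show the mechanism
works where communities are the dominant structure, not that the method is
universally calibrated.

## Spreading ability

Discrete-time SIR: one uniformly random seed node; each infected node
transmits to each susceptible neighbour independently with probability p,
then recovers permanently. The reported index is the mean outbreak size
(nodes ever infected) over 1000 runs by default. p defaults to
1.5 ⟨k⟩/(⟨k²⟩ − ⟨k⟩) — 1.5× the heterogeneous mean-field epidemic
threshold — so outbreaks are supercritical but not saturating, which keeps
the index sensitive to the inserted links. This parameterisation is a
package choice; spreading values are Monte-Carlo estimates and are treated
as such (seeded, never compared at fixed precision).

## Numerical and interface choices

* Node identifiers are opaque; pairs are canonicalised by the string order
  of their endpoints, which also fixes all tie-breaks deterministically.
  Zero-score candidates are likewise ordered lexicographically rather than
  shuffled — determinism was preferred over tie randomisation.
* All replicate randomness derives from a base seed via a fixed integer
  mixing scheme (children stay below 2³¹), so every experiment is
  reproducible end to end.
* Edge lists are whitespace-delimited text, `#` for comments; duplicate
  lines collapse with a warning, self-loops are hard errors.
* Problem sizes in the test suite are deliberately moderate (30 replicates
  for the β-trend checks, 10 for parameter recovery, 20–50 realizations for
  detection robustness, 21-point β grids); they are chosen so the full
  suite documents the behaviour at desk scale.

## Known limitations

* The EO detector is a stochastic heuristic; on graphs with weak or
  ambiguous community structure different seeds can return different
  partitions, and the method's premise itself breaks down on networks
  without communities (β-interleaving then degenerates to the plain
  ranking).
* ⟨B⟩-matching assumes ⟨B⟩(β) is monotone enough for a nearest-point match
  to be meaningful; on very small learning sets the curve is noisy and β̂\*
  inherits that noise.
* Congestibility and synchronizability are specific operationalisations
  (maximum node betweenness; Laplacian eigenratio); other definitions exist
  and would change the reconstruction comparison quantitatively, not
  qualitatively.
* Weighted, directed and bipartite graphs are out of scope, as are global
  similarity indices and spurious-link detection.
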