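# Methods

## Scope and model

`gotkit` characterizes an evolving network by the trajectory of its
nodes' subgraph roles. The underlying model of a temporal network is a
sequence of undirected simple-graph snapshots with *active-edge*
semantics: an edge belongs to the snapshot in which it is observed and
must re-appear to persist. Snapshot indices are 0-based contiguous
integers; indices missing from an edge list denote empty snapshots. The
optional start time and interval width of the observation window are
carried as metadata only — no computation uses them. Self-loops are
dropped (with a logged warning) rather than rejected, since real edge
lists often contain them.

## Catalogs, canonical codes and orbit numbering

All non-isomorphic connected k-graphlets (undirected k ≤ 6, directed
k ≤ 4) are enumerated by scanning every labeled graph on k vertices. The
canonical code of a graph is the minimum adjacency bit string over all
relabelings compatible with an iterated neighbourhood-degree (WL-style)
colour refinement; restricting to colour-compatible relabelings is sound
because the refinement is an isomorphism invariant, and the exhaustive
permutation fallback (at most k! = 720) keeps the code exact. We chose
exhaustive search over an external canonical-labeling tool because at
these sizes determinism and auditability matter more than speed: the full
k = 6 undirected catalog (32 768 labeled graphs) builds in about two
seconds. Directed connectivity means weak connectivity; reciprocal arcs
are allowed. Directed catalogs for k ≥ 5 are refused — the transition
state space (> 44k orbits squared) is impractical to store or interpret.

Orbit ids are global, deterministic and 1-based: graphlets are sorted by
(edge count, canonical code) and orbits within an undirected graphlet by
descending representative degree (position index breaks ties). The
undirected k = 4 catalog is additionally pinned to the conventional order
star, path, cycle, paw, diamond, clique, so that the star centre is orbit
1, the star leaf 2, the cycle orbit 5 and the clique orbit 11; with
high-degree orbits leading, a star centre that gains one edge between its
leaves lands in orbit 6 (the paw hub) and one that gains two lands in
orbit 9 (the diamond hub). The full numbering is part of the catalog JSON
export, so downstream consumers never have to re-derive it.

## Census

Connected induced k-subgraphs are enumerated by ESU-style recursive
extension: a subgraph rooted at v grows only through nodes with id
greater than v that lie outside the closed neighbourhood of the current
subgraph, which yields every connected k-set exactly once. We use ESU
rather than a compressed-trie enumerator because the output contract —
the set of induced occurrences and their per-node orbits — is identical
and ESU is straightforward to verify against an all-subsets oracle, which
the test suite does on random graphs up to n = 12 for k ∈ {3, 4, 5}.
Occurrences are streamed, never materialized, and the per-occurrence
orbit lookup is a cached map from the induced adjacency bit mask to the
orbit tuple, so the canonical search is paid at most once per distinct
k-subgraph shape.

From the occurrence stream we derive the node × orbit frequency matrix
Fr (rows are graphlet degree vectors), the graphlet degree distribution
GDD (per-orbit histogram of Fr entries at multiplicities p ≥ 1) and the
node degree distribution, which coincides with the degree-orbit line of
the 2-node GDD.

## Transition matrices

Occurrences of consecutive snapshots are indexed by their sorted integer
node tuple and intersected; each matched k-set contributes k transitions
(orbit at t → orbit at t+1), including self-transitions, which populate
the diagonal and measure role stability. Sets connected in only one of
the two snapshots contribute nothing — once a group disconnects it is no
longer a group — and nodes that leave the network simply never match.
Only consecutive pairs (t, t+1) are compared. A set may change graphlet
between snapshots (path → triangle); transitions are orbit-to-orbit, not
graphlet-restricted. Memory stays bounded by two snapshots' occurrence
indexes.

Row normalization divides each row of T by its sum and leaves all-zero
rows at zero — an orbit never seen at time t carries no evidence, and
mapping its row to zero (rather than uniform) keeps OTA's "no difference"
reading for orbit pairs absent from both networks. For visualization,
normalized rates are discretized into rare [0, 1/3], common ]1/3, 2/3]
and frequent ]2/3, 1] bands.

## Agreement metrics

OTA is the mean elementwise agreement 1 − |ntr_a − ntr_b| over the |O|²
cells of two row-normalized matrices; it is symmetric, bounded in [0, 1]
and equals 1 exactly on identical matrices. nOTA min-max rescales an OTA
matrix over the *off-diagonal* pairs of a network set (including the
diagonal would pin the maximum at 1 trivially); the self-diagonal is
reported as 1, and a degenerate set with all agreements equal maps to all
1 with a warning rather than an error.

GDD-agreement normalizes each network's GDD by its grand total, pads the
multiplicity axes to the larger observed maximum, scores each orbit as
1 − (1/√2)·‖nG_j − nH_j‖ and averages over orbits. No 1/p weighting is
applied: the total-area normalization is used as-is, which differs from
some of the older graphlet-agreement literature — the two networks being
compared are treated symmetrically either way.

Motif fingerprints score each graphlet class by
δ = (Fr − ⟨Fr_null⟩)/(Fr + ⟨Fr_null⟩) against the mean of a
degree-preserving null ensemble (double-edge swaps; self-loops and
duplicate edges rejected; a fixed budget of 10·|E| attempted swaps per
replicate, with 100 replicates by default). δ is defined as 0 when both
frequencies vanish, avoiding NaNs for graphlets the network can never
realize, and the fingerprint is δ scaled to unit norm. Fingerprints are
compared by Euclidean distance. Significance z-scores are deliberately
out of scope — the δ score is the fingerprint.

## Synthetic evolving-graph models

The generator suite emulates six reference conditions: Erdős–Rényi and
Barabási–Albert growth with deletion noise P(e−) ∈ {0, 0.5}, and
Watts–Strogatz rings with rewiring β ∈ {0, 0.2}. Defaults are 5
snapshots, 250 starting nodes, 10% node growth per snapshot (floor
rounding, new ids appended) and density E/N² = 0.01 enforced exactly per
snapshot by rounding for the Erdős and Barabási families. Each snapshot
transition grows the node set, deletes each surviving edge independently
with probability P(e−), then adds edges — uniformly at random, or with
both endpoints drawn proportionally to degree+1 so isolated newcomers can
attach — until the density target is met. The Strogatz family instead
maintains a ring lattice whose even degree is fixed from the initial
size (nearest even integer to 2·density·n0, half rounded up: 6 at
n0 = 250); new nodes are spliced into uniformly random ring positions and
wired to their nearest ring neighbours, and each edge is independently
rewired with probability β per snapshot (one endpoint kept, the other
resampled uniformly, collisions rejected). The ring structure fixes the
Strogatz edge count at n·r/2, so its density is approximately — not
exactly — stable; the exact per-snapshot edge-count contract applies to
the Erdős and Barabási families only. One master seed drives a suite;
per-network seeds are derived by a fixed counter scheme, and the same
spec always regenerates the identical network.

What the generators do *not* emulate: community structure, degree
assortativity, weighted or directed edges, and bursty edge timing.
Passing the grouping benchmark on these models therefore shows that the
fingerprints separate canonical growth mechanisms at matched size and
density — not that they resolve arbitrary real-world categories.

## Grouping benchmark

Each network is summarized by one feature row — normalized motif scores
on the aggregate (SM), aggregate orbit totals (SG), concatenated
per-snapshot orbit totals (STG) or the flattened transition count matrix
(GoT) — centred and PCA-reduced to the smallest component set holding
99% of the variance, with pairwise Euclidean distances min-max rescaled
to [0, 1] over the off-diagonal pairs. The network is the default unit of
comparison: a per-node description is internally inconsistent for SM,
which is a network-level fingerprint, so the node-level mode (per-node
GDV or per-node transition vectors, networks summarized by their mean
node vector) is offered for SG and GoT only. A threshold ε sweeps 0 to 1
in steps of 0.001; pairs at distance ≤ ε are grouped, precision is the
same-label fraction of grouped pairs (1 before any pair is grouped, so
the curve starts at (0, 1)), recall the grouped fraction of all
same-label pairs, and AUPR the step sum Σ Pr(k)·ΔRec(k). Class imbalance
is not corrected. Agreement matrices are clustered by complete linkage on
1 − agreement.

The in-repo benchmark runs the six model conditions at a reduced scale
(n0 = 100, 5 replicates, 5 master seeds) so the whole suite stays within
an ordinary test budget. A caveat discovered while validating at this
scale: holding the density parameter at 0.01 while shrinking n0 from 250
to 100 lowers the mean degree from 5 to 2, which pushes the
deletion-noise conditions below the percolation threshold — almost no
4-node set stays connected across consecutive snapshots, so the
transition fingerprint loses most of its signal there while the static
baselines keep reading aggregate density. At intermediate sizes
(n0 = 150, mean degree 3) the transition fingerprint leads the static
baselines again. The reduced-scale benchmark therefore probes the
pipeline end to end but is not a faithful miniature of the full-scale
comparison regime.

## Numerical and degenerate-input choices

* Edge targets use banker's-free rounding of density·N²; node growth uses
  floor.
* PCA of an (effectively) constant feature matrix returns a single
  all-zero component; requesting 100% variance keeps all components.
* An all-equidistant unit set yields an all-zero distance matrix with a
  warning; precision-recall refuses single-class inputs (recall would be
  undefined).
* Orbit ids are 1-based everywhere user-facing; internal arrays are
  0-based.
* Degree-preserving randomization of a graph with no valid swap (e.g. a
  triangle) returns it unchanged.
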