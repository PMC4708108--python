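# Methods

## State space and topology

A structure over a sequence of length n is a set of base pairs (i, j),
1-based, i < j, each index paired at most once, with the hairpin constraint
j − i ≥ 4 (at least three unpaired nucleotides inside a closing pair). Only
canonical pairs (AU, GC, GU and their reverses) are admitted once a
structure is bound to a sequence; the purely combinatorial checks happen at
construction so that structure files can be validated independently of any
sequence.

Crossing pairs are restricted to the 1-structure class. A structure is
decomposed into helices (maximal stacks of consecutively nested pairs);
helices are vertices of the conflict graph, with an edge whenever two
helices' outermost pairs interleave. A structure is admissible iff every
conflict-graph component, reduced to one chord per helix, has topological
genus exactly 1. Genus is computed by boundary tracing of the fattened
one-backbone diagram: each chord endpoint contributes a left and a right
flank point, boundary arcs connect flanks along the exposed backbone,
around the backbone ends, and along the two sides of each fattened chord;
the number b of cycles of this 2-regular arc system gives
g = (c − b + 1)/2. The implementation is cross-checked in the tests against
an independent permutation-cycle (Euler characteristic) oracle on every
diagram with up to five chords.

Component *types* are assigned on shadows: one chord per helix, adjacent
nested chord pairs (stacks) collapsed repeatedly — a reduction that
provably changes neither crossing sets nor genus. Exhaustive enumeration
(in the test suite, up to six chords) confirms that exactly four
irreducible genus-1 shadows exist; they define the H, K, L and M component
types, and a structure's composite class is the sorted set of its component
types ('N' when crossing-free).

The membership test for single-pair additions is local: only the
chord-crossing component absorbing the new pair can change, and the genus
of a chord component equals the genus of its helix shadow, so one genus
evaluation on a small chord set decides admissibility. The equivalence of
the chord-level and helix-level tests was verified exhaustively on random
pair sets during development and is property-tested in the suite.

## Energy model

The free energy of a structure is

    f(x) = Σ_helices [ end_penalty + Σ_stacks stack(p, q) ]
         + Σ_components β_type ,

with the open chain at 0. The default stacking table is generated from
per-pair-type stabilities (GC 3.3, AU 1.1, GU 0.7 kcal/mol) as
stack(p, q) = −(s(p) + s(q))/2; the helix-end penalty is +2.0 kcal/mol; the
pseudoknot penalties default to β_H = 9.6, β_K = 12.6, β_L = β_M = 14.6
kcal/mol and must satisfy β_H ≤ β_K ≤ min(β_L, β_M). T = 310.15 K and
R = 1.98717×10⁻³ kcal/(mol·K), so RT ≈ 0.6163 kcal/mol. Dangles, coaxial
stacking and special loops are deliberately absent: no landscape algorithm
depends on them, and the simple model keeps every fixture exactly
enumerable. An adapter hook (`EnergyParams.nested_hook`) lets an external
nearest-neighbor evaluator replace the crossing-free part without touching
the pseudoknot penalties or any algorithm above the energy interface.

Two structural consequences of the defaults are load-bearing and tested:
energies are additive over conflict components, and β_H exceeds the largest
possible single-move gain (two stacking terms plus a released end penalty,
8.6 kcal/mol), so the first crossing pair added to a crossing-free
structure is always strictly uphill — gradient walks started from
crossing-free structures therefore cannot end in pseudoknotted minima.

## Landscape algorithms

Adjacency is the single base-pair move. The 1-structure class is closed
under pair removal, which yields three useful facts: subset backtracking
enumerates the ensemble completely; every structure is connected to the
open chain; and within a fully enumerated ensemble the adjacency relation
is recovered for free (each structure's neighbors are itself minus one
pair), which the flooding oracle and the microscopic kinetics both exploit.

Gradient walks take the lowest-energy neighbor, ties broken removals
first, then lexicographically by (i, j) — a total order, so the walk is a
pure function of the start. Boltzmann-weighted minimum discovery samples
exactly from the enumerated ensemble when the sequence is enumerable
(guarded at 40 nt) and otherwise by Metropolis MCMC over the move set with
a Hastings correction for the position-dependent neighborhood size
(burn-in 1000, thinning 10 by default). The MFE basin is always injected.

## Saddle estimation and the BHG

findpath-style search: only moves that reduce the base-pair distance to
the target are considered, so paths have exactly d(x, y) moves. A beam of
the `width` lowest-peak partial paths is kept per distance level; the
search runs at doubling widths up to `width` and keeps the best result,
making the returned peak non-increasing in `width` by construction.
Profile-unimodality is *not* enforced during search — the optimal path
between two minima routinely dips through intermediate valleys, and
enforcing a monotone profile was observed to inflate saddle estimates
catastrophically — but among equal-peak results a monotone up-then-down
witness is preferred.

`estimate_saddle` gradient-walks every structure on the path; each newly
discovered minimum z splits the problem into (x, z) and (z, y), recursed to
`rounds` levels (default 3), and z is admitted whenever it strictly lowers
the composite saddle. Estimates are memoized per unordered pair and are
symmetric and non-increasing in `rounds`.

`build_bhg` estimates saddles for all pairs among the `k_lowest` (default
50) lowest minima plus every minimum's nearest neighbor by base-pair
distance, folds discovered minima back into the node set (up to three
sweeps), and then prunes dominated edges. An edge (x, y) is dropped when a
third minimum z with f(z) < S(x, y) routes the transition at no higher
saddle *and* the edge's own witness path passes through z's basin — the
direct transition is then not an elementary basin hop. The witness
condition matters: when several basins merge at one tie level, a bare
max(S(x,z), S(z,y)) ≤ S(x,y) test deletes every edge in the tie cluster
and disconnects the graph. Saddle values are reported to 0.01 kcal/mol;
pairwise saddles between non-adjacent nodes are minimax closures over the
edge weights.

BHG° re-runs the whole construction on the crossing-free minima with
additions restricted to non-crossing pairs. Exact flooding processes the
enumerated ensemble in order of (energy, lexicographic) and merges basins
by union-find; the merge level is the exact minimal saddle between every
pair of minima joined there, and the merge events form the barrier tree,
whose minimax closure reproduces the exact saddle matrix (the exact-mode
BHG uses precisely these tree edges).

## Kinetics

Row-vector convention p′ = pR: R[y, x] = r0·exp(−(S(x,y) − f(y))/RT) on
BHG edges (the state whose energy appears in the exponent is the source;
this orientation is the one fixed by detailed balance, which the
construction then satisfies exactly: both directed fluxes equal
e^(−S/RT)). The microscopic oracle uses Metropolis rates
r0·min{1, e^(−Δf/RT)} on the single-move graph. Propagation exploits
reversibility: with D = diag(π), M = D^(1/2) R D^(−1/2) is symmetric, one
`eigh` gives every time point. Two numerical choices matter: the stationary
eigenvalues (one per connected component, counted via the support graph)
are pinned to exactly 0, because O(1e−16) rounding would visibly decay the
equilibrium at times beyond ~1e12 r0⁻¹; and the generator spectrum is
clipped at 0 from above. Probability is conserved to ~1e−13 over the
default grid (log-spaced, 1e−2…1e18 r0⁻¹, 60 points/decade capped at 600).

QSS reduction repeatedly eliminates the non-protected state with the
lowest degree (highest energy on ties), redistributing flux by
r′(a→b) += r(a→q)·r(q→b)/λ_q — the Schur complement of the generator,
which preserves reversibility and the restricted equilibrium exactly. The
MFE minimum, the start state and user-marked states are protected; the
default cap is 5000 states, and reports by default show only states whose
population ever exceeds 7%.

## Refolding paths

Criterion A computes the bottleneck (minimax) saddle first, restricts to
edges at or below it, and then takes the least accumulated-activation
path by Dijkstra with non-negative weights S − f(source); ties break on
fewer edges, then the node-id sequence. Peaks are evaluated on edge
saddles, where BHG paths attain their maxima. Criterion B maximizes
L(U) = Π r(x_i→x_{i+1}) · e^(−(Σ λ_i t_i + λ_k (T_m − Σ t_i))). At
T_m = 0 this is exactly the minimum accumulated-activation path (log r =
−(S − f)/RT). For T_m > 0 the exponent is linear in the waiting times over
a simplex, so per state sequence the optimum sits at a vertex: the whole
slack goes to the visited state with minimal total exit rate (earliest on
ties). Only simple paths are searched; revisiting a state multiplies extra
rate factors ≤ 1 into L and can never help. Both claims are checked
against brute-force path-and-time enumeration on small graphs.

## Designed fixtures and what they show

All tests run on designed sequences whose landscapes are exactly
enumerable (≤ ~25 nt, mostly {G, C, A} alphabets so that A-linkers are
chemically inert): single hairpins, two-hairpin switches, H-type and
K-type block arrangements. Expected properties are recomputed by the
enumeration and flooding oracles at fixture-build time, never hand-written.

Two fixtures deserve explanation:

* **pk_shortcut** demonstrates a pseudoknotted refolding shortcut: with
  crossing 3-pair GC helices and β_H lowered to 4.0 kcal/mol (the ordering
  invariant still holds), the cheapest path between the two hairpin minima
  passes the H-type intermediate at peak +1.4 kcal/mol, while the
  crossing-free route must climb +2.0 kcal/mol through the open chain. With
  the default β_H — which by design exceeds any single-move gain — no
  enumerable-scale landscape can exhibit such a shortcut: helices deep
  enough to amortize the default penalty need so many complementary
  positions that exhaustive enumeration becomes infeasible. The reduced
  penalty is part of this fixture's definition, chosen by the peak algebra
  above, not fitted to any test outcome.

* **qss_ring_model** is an abstract 20-state generator (10 deep cores on a
  ring, connected through 10 high-energy degree-2 intermediates, plus
  direct core chords) realizing the textbook quasi-steady-state situation
  in which the degree criterion provably selects the right states.

The kinetics-validation fixtures use 2-pair stems. The reason is a real
limitation of the Arrhenius approximation worth stating plainly: the
coarse rates carry a prefactor of r0 per edge, while the microscopic exit from a
basin proceeds through *all* parallel saddle-level channels. For a basin
entered through m distinct single-pair nucleation states the effective
microscopic rate is ~m·r0, shifting the transient by log10(m) decades.
With 2-pair stems m ≈ 2 and the coarse populations track the microscopic
ones within 0.05 absolute on the full grid; with 3-pair stems (m ≈ 4–6)
the transient deviation grows to ~0.1, and on larger multi-helix
landscapes it grows further. Passing the kinetics tests on the designed
fixtures therefore shows the construction is correct and the approximation
sound where its assumptions (few parallel channels, separated time
scales) hold — it does not bound the transient error on arbitrary real
RNA landscapes, where barrier heights are larger but channel multiplicity
is too.

Problem sizes used throughout: ensembles of 10²–10⁵ structures per
fixture; 20 fixtures in the saddle-agreement battery; log-time grids of
8–10 points per decade over 1e−2…1e18 r0⁻¹ for validation runs. These are
the package's chosen study conditions for exact-oracle comparability.

## Known limitations

* The energy model is structural, not thermodynamically calibrated;
  absolute energies and rates are not comparable to experiment, only the
  landscape algebra on top of them is.
* Boltzmann sampling by MCMC mixes slowly across deep basins (as any
  local-move sampler must); discovery of minima behind large barriers at
  low temperature requires large sample counts or the exact enumerator.
* Shift moves, co-transcriptional folding, base triples and components of
  genus ≥ 2 are out of scope.
* Criterion-B optimization fixes the state sequence to the minimum
  accumulated-activation path before allocating waiting time; a sequence
  that sacrifices rate product for a smaller exit rate could in principle
  win at very large T_m, though the brute-force checks on small graphs did
  not produce such a case.
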