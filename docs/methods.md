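# Methods

## Model and scope

The package treats a network as a directed, binary graph on N nodes with
no self-connections: an adjacency matrix **A** with entries in {0,1} and a
zero diagonal. Weighted or multi-edge inputs are binarized (any nonzero →
1) with a logged warning; weighted "subgraph intensity" analyses are out
of scope. All subgraph statistics are raw counts — no significance
filtering against a null is built into the definitions; null comparisons
are a separate, explicit step (`nullmodels`).

Two occurrence semantics run through everything:

- **functional** (partial, edge-induced): a pattern occurs on a node
  triple whenever its edges are a subset of the edges present; each
  distinct edge subset counts once;
- **structural** (induced): the triple's full edge set must equal the
  pattern; each connected triple therefore contributes to exactly one
  motif class and each of its nodes to exactly one role.

Counting is per automorphism class of embeddings, i.e. per edge *subset*,
not per node mapping: a node with k in-neighbors heads C(k,2) convergent
pairs, not k(k−1). This is what makes role counts of a motif sum to
plurality × motif count.

## Catalog and numbering

`catalog` enumerates every directed graph on 3 (or 4) labeled nodes,
keeps the weakly connected ones, and groups them by exhaustive
minimization of the adjacency bitmask over all node permutations. Weak
connectivity is the reading that yields the canonical 13 triad classes
(strong connectivity would not), and the same machinery yields 199
connected classes on 4 nodes. Node roles are automorphism orbits,
computed from the automorphism group directly; the 13 classes carry 30
orbits.

The public ids (motifs 1–13, roles 1–30) are fixed by a shipped registry
(`data/numbering_registry.tsv`) built from explicit pattern tables and
validated at load time. Anchored entries: motif 2 = two-path, motif 5 =
cyclic triangle, motif 9 = feed-forward triangle, motif 13 = complete
triad; roles group into the 9 ego-pattern families ({out}, {in}, {recip},
{in,in} from 10, {out,out} from 13, {in,out} from 16, {recip,out} from
20, {recip,in} from 24, {recip,recip} from 28), ordered within a family
by required cross-edge count. Orientation ties inside a family are fixed
by a package convention (pattern-forward first: role 17 is the
feed-forward middle, role 18 the cycle role; roles 21/25 put the
dyad-partner → other cross edge before its reverse). Each registry row is
tagged `pinned-by-text` or `package-convention` so downstream users can
see which ids are load-bearing. Nothing in the algebra depends on the
tie-break choices: the conversion matrices, clustering formulas and tests
all reference roles through the registry.

## Functional fingerprints: the fast path

All 30 functional rows are computed from **A**, its transpose, and the
reciprocal matrix **R** = **A** ∘ **Aᵀ** with a handful of dense integer
matrix products — no triple enumeration:

- the nine "hanging third node" roles (families {out}, {in}, {recip}) are
  matrix–vector products such as A·d_out − d_recip;
- the six degree-pair roles are closed forms: C(d_in,2), C(d_out,2),
  d_in·d_out − d_recip, d_recip(d_out−1), d_recip(d_in−1), C(d_recip,2);
- the fifteen triangle-closure roles are diagonals of triple products,
  each evaluated as one matmul plus a Hadamard mask
  (diag(XYZ) = ((XY) ∘ Zᵀ)·1), with a factor ½ where the two
  non-reference positions are symmetric.

The O(N³) brute-force census (`role_fingerprints_bruteforce`) classifies
every node triple through a precomputed 64-state lookup table and is kept
as the independent oracle; the suite asserts exact integer equality
between the two on 50 seeded random digraphs (N=25, p ∈ {0.05, 0.2,
0.5}) plus all toy fixtures. The brute-force path guards N ≤ 2000 by
default (configurable) — beyond that the fast path is the only sensible
route.

## Conversion matrices

`derive_role_conversion` enumerates, for each of the 30 role patterns,
its weakly connected spanning edge subsets (≤ 2⁶ per pattern) and
classifies each with the reference node held fixed; entry (s, f) of the
resulting 30×30 matrix counts copies of functional pattern f inside
structural pattern s. Sorting patterns by edge count makes the matrix
triangular with unit diagonal, hence unimodular, so its inverse is
integer-valued and `functional → structural` conversion is exact. The
13×13 motif-level matrix is the same construction without a reference
node. The applied convention is functional(f) = Σ_s T(s,f)·structural(s),
i.e. F = Tᵀ S.

A negative or non-integer entry in a converted "structural" result is
diagnostic: the input was not a realizable functional statistic of any
graph, and the package raises rather than clips.

`empirical_conversion` recovers the same matrices from data alone: stack
per-node functional and structural fingerprints of sampled random graphs
and solve the linear system by least squares, rounding to integers. It
exists for pattern sizes where the combinatorial derivation has not been
carried out (4-node and beyond); at the 3-node level the tests require it
to reproduce the combinatorial matrices exactly from 100 random graphs
(N=15, p=0.3). Rank deficiency (e.g. all-empty samples) is an error, not
a warning.

Both matrices, both directions, ship as TSVs under `data/`, written by
the derivation code; a test regenerates them and compares byte-for-byte.

## Clustering and transitivity

Every numerator and denominator is a role-count expression; degrees enter
only through identities that the role counts already satisfy
(D = d_tot(d_tot−1) − 2 d_recip = 2(F10+F13+F16) per node). The six
per-node coefficients and their formulas are listed in the module
docstring; the factors of 0.5 on the in/out subtypes reflect the two
possible edges that close a convergent or divergent pair into a
feed-forward triangle. The 3-feedforward subtype is defined as the
role-consistent blend (F11+F14+F17) / (2F10+2F13+F16) — all three
feed-forward roles over all their closure opportunities — which reduces
to the in/out/middleman definitions on nodes exposing a single role and
reads as the fraction of possible non-cyclic closed triangles. Zero
denominators yield zero coefficients.

Global means are reported both over all N nodes and over the n* nodes
with nonzero denominator; the n* variant is the headline number.
Transitivities are ratios of network totals (sum of numerators over sum
of denominators), a deliberately different estimator from the mean of
per-node ratios; the two coincide on vertex-transitive fixtures, which
the suite checks. The cycle transitivity's denominator is the total
two-path count — identical whichever of motif 2's three roles is summed,
also asserted. Undirected transitivity is computed from structural motif
counts (3 × triangle-projection classes over the triangle-weighted triad
census) and equals networkx's transitivity of the collapsed graph to
machine precision.

Structural-flavor clustering coefficients (same formulas, induced counts)
are exposed behind `allow_structural=True` as an experimental variant and
excluded from all headline outputs.

## Null models and overabundance

`randomize_degree_preserving` performs double-edge swaps with rejection
of self-loops and duplicate edges; in/out-degree sequences are preserved
exactly, reciprocal degree deliberately not. The attempt budget defaults
to 100× the edge count — a standard mixing heuristic; the value is a
parameter, not a finding. A graph that admits no successful swap (e.g. a
3-cycle) is returned unmodified with a flag and warning. An optional mode
preserves reciprocal degree too, by swapping within the single-edge and
reciprocal-pair families separately; it is off by default to match the
plain in/out-degree null. Ensembles use consecutive seeds from a base
seed so each replicate is independently recomputable; summaries report
means and sample standard deviations, with no parametric test implied.

Overabundance reports observed functional role counts against the null
mean per (node, role), with an optional division by total degree
(isolated nodes report 0, never NaN). Because the null preserves in/out
degrees, roles 10 and 13 are exactly invariant across replicates — the
suite asserts this — while role 16 = d_in·d_out − d_recip varies with the
reciprocal degree the swaps destroy, so its invariance is *not* asserted
or assumed anywhere.

## Synthetic data

`random_digraph` generates the test bed: independent Bernoulli(p) edges
per ordered pair, or, with a reciprocity parameter ρ, per-unordered-pair
states {none, single, reciprocal} with P(reciprocal) = pρ and P(single) =
2p(1−ρ), keeping the marginal edge probability at p while P(an edge is
reciprocated) = ρ. Test densities (p between 0.05 and 0.9, N between 15
and 80, ρ ≈ 0.25–0.4) bracket sparse connectome-like regimes and dense
stress cases. What this generator does *not* emulate: degree
heterogeneity beyond binomial, community structure, or distance-dependent
wiring — so green tests certify the counting and conversion algebra
(which is exact for any binary digraph), not any claim about real
networks' motif content. Exactness is the point: every oracle comparison
in the suite is integer equality, and problem sizes (N ≤ 80 for nulls,
N=25 panels for the oracle, 100 × N=15 for the empirical derivation) were
chosen as the smallest that exercise all 30 roles at nonzero counts.

## Numerical choices and limitations

- All counting in int64; matmul-based diagonals stay exact well beyond
  any realistic 3-node count.
- Conversion inverses are computed in floating point, rounded, and
  verified by exact integer multiplication back to the identity; a
  determinant other than ±1 is an error.
- Canonicalization is exhaustive over k! permutations and deliberately
  capped at k = 4; 5-node catalogs are out of scope.
- 4-node classes (199) and their orbits are enumerable with the same
  machinery but carry no shipped numbering or conversion matrices; the
  empirical route is the intended path for users who need them.
- The CLI prints ratios at 12 significant digits and records package
  version, seed and a config hash in every artifact header; logs go to
  stderr only.
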