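# Methods

## The model

A *generator* G is a small connected simple graph with two designated root
nodes R1, R2. The generation-t network G_t is obtained from G_{t-1} by
replacing every edge with a fresh copy of G, identifying the edge's
endpoints with the roots; G_0 is a single edge whose endpoints are the
*renormalized root nodes* (RRNs) of every later generation. This growth is
the inverse of the renormalization map that coarse-grains generator-shaped
subgraphs into superedges, which is what makes the networks exactly
self-similar and the percolation problem exactly renormalizable.

Deterministic growth requires: (1) both root degrees κ1, κ2 ≥ 2, (2) root
distance λ ≥ 2, (3) root symmetry (deleting either root yields isomorphic
graphs, decided exactly by VF2 at generator scale). Violations are
warnings: sizes, clustering and the joint degree distribution survive; the
degree-exponent, fractal and correlation sections become inapplicable.
Asymmetric generators grow stochastically — each edge replacement orients
the roots by a fair coin — and all structural tables become ensemble
expectations.

Everything closed-form is driven by integer descriptors of G alone: edge
and node counts m_gen, n_gen (n_rem = n_gen − 2 remaining, i.e. non-root,
nodes), root degrees and their mean κ̄ = (κ1+κ2)/2 and half-difference
κ̌ = |κ1−κ2|/2, root distance λ, remaining degree sequence {k_n} with
K2rem = Σ k_n², triangle counts Δ_gen and per-root Δ_R1, Δ_R2, the mean
local clustering C_rem of remaining nodes, per-root neighbour degree
profiles μ1(k), μ2(k) (μ_i sums to κ_i), and the remaining-to-remaining
edge census m_rem(k, k′).

## Structure theory

**Sizes.** M_t = m_gen^t and N_t = 2 + n_rem(m_gen^t − 1)/(m_gen − 1),
exact integers, independent of symmetry.

**Degree tables.** A degree-k node of G_{t−1} becomes degree κk (symmetric)
while each replaced edge injects the remaining nodes. The symmetric table
is evaluated in closed form (two root-lineage nodes of degree κ^t plus
geometric waves of remaining-node descendants). Asymmetric generators
multiply each of a node's k edges independently by κ1 or κ2 with
probability 1/2, i.e. binomial redistribution; the expected table is
iterated as a dense array over degrees (range grows like max(κ1,κ2)^t,
capped at 2·10^6).

**Moments and exponents.** ⟨k⟩_t = 2M_t/N_t always; ⟨k²⟩ has an exact
rational closed form with a separate branch at m_gen = κ², and the
infinite-generation second moment is finite iff m_gen > κ̄². The degree
distribution has exponent γ = 1 + log m_gen / log κ̄ (≥ 2 always, since
m_gen ≥ 2κ̄); the count-table exponent is γ′ = γ − 1 when κ1 = κ2
(degrees exponentially spaced) and γ′ = γ otherwise (degrees dense). The
fractal dimension is D_f = log m_gen / log λ, infinite (small-world) when
the roots are adjacent.

**Clustering.** All triangles of G_t arise inside the last wave of
generator copies. The average clustering coefficient splits into the
fresh remaining-node term (mean C_rem) and the inherited-node term driven
by per-root triangle counts; its symmetric infinite limit is the series

    C_∞ = (m_gen−1)/m_gen [ C_rem + 2Δ_R/(κ n_rem)
          Σ_n Σ_{s≥1} 1/((κ m_gen)^s k_n − m_gen^s) ],

truncated when a term falls below 1e-15 (the terms decay geometrically,
faster than (κ m_gen)^{-s}, so the discarded tail is below the truncation
level). The global coefficient (transitivity) follows from the triangle
total M_{t−1}Δ_gen and the moment formulas; its limit vanishes whenever
⟨k²⟩ diverges and is otherwise an exact rational in the generator's own
degree moments. Asymmetric finite-t values take a binomial mixture over
orientations with h(k, k1) = κ1 k1 + κ2(k − k1) as the inherited degree;
the asymmetric limit is obtained by iterating generations until successive
values differ by < 1e-6 (convergence is geometric, about one factor of
m_gen per generation; G^C settles by t ≈ 8).

**Joint degree distribution and correlations.** The table P_t(k, k′) over
ordered end-degree pairs combines the remaining-to-remaining edge census
with inherited-node edges counted through μ1/μ2 (read per single root;
this reading reproduces the generator's own edge census at t = 1 exactly).
Assortativity is the Pearson correlation of end degrees under P_t;
Spearman's coefficient is the Pearson correlation of mid-rank grades
(standard tie handling). Infinite limits iterate t until successive values
move < 1e-4; the assortativity limit is 0 outright when m_gen ≤ κ̄³
(degree exponent ≤ 4, divergent third moment). Symmetric tables are exact
fractions end to end.

**Multiple generators.** When each edge independently picks generator i
with probability p_i, γ and D_f keep their forms with ⟨m_gen⟩, ⟨κ̄⟩ and
⟨λ⟩ in place of the single-generator descriptors.

## Percolation renormalization

Keeping each edge with probability p renormalizes exactly: the RRN
connection probability obeys R_t = π(R_{t−1}) with the two-terminal
reliability polynomial π(p) = Σ_m s_m p^m (1−p)^{m_gen−m}, where s_m
counts m-edge subsets connecting the roots. s_m is enumerated exhaustively
(bitmask over subsets, union-find connectivity, cap 24 edges) on the *core
subgraph* — the edges lying on at least one simple root-to-root path,
found by exhaustive path enumeration — since off-core edges cannot affect
root connectivity; generators sharing a core share all percolation
quantities. The threshold is the unstable fixed point π(p_c) = p_c with
π′(p_c) > 1, located by a sign-change scan on a 10^4-point grid plus
bisection to 1e-12; several unstable roots would be reported as an error
rather than silently resolved, and a core whose fixed points all sit at
the ends (e.g. trees) reports "no transition below 1". Exponents:
ν = log λ / log π′(p_c), ν̃ = log m_gen / log π′(p_c) (full m_gen — size
growth is by m_gen even when the polynomial degree is reduced), with
ν̃ = D_f ν holding identically.

**Order parameter.** The probabilities S_t (a random node touches exactly
one RRN) and T_t (both) propagate linearly, (S_t, T_t)ᵀ = W (S_{t−1},
T_{t−1})ᵀ. The entries of the 2×2 matrix W are assembled from coefficients
c_ij(m): for each removed host edge e0 (the walker's own copy sits on e0)
and each subset of the other m_gen − 1 edges treated as percolating copies
(weight R each), we count configurations where exactly i ∈ {1,2} roots are
reachable from the attachment set — a single terminal of e0 for j = 1
(both terminal choices counted; the 1/(2 m_gen) prefactor averages them),
or both terminals merged for j = 2. β = −log ω_c / log π′(p_c) with ω_c
the largest eigenvalue of W at p_c, computed by the closed-form quadratic.
This S/T reading is the one consistent with P_t = S_t + T_t, and it
reproduces the independently printed eigenvalues for both symmetric
reference generators, which was used as the arbiter between readings.

## Builder and simulation

Nodes are identified by flat tuples (generation of birth, parent-edge
index in the lexicographically sorted edge list of the previous
generation, generator-local label), so builds are reproducible and
diffable without global counters. Randomness (generator selection,
orientation flips) comes from one stream per (seed, generation) consumed
in canonical edge order, making results independent of iteration order; a
single symmetric generator consumes no randomness and builds bit-identical
graphs for every seed. A node-count guard (default 10^7) precedes each
build. A custom initial graph is accepted (e.g. a star, recovering the
two-star family's classical construction), in which case the size closed
forms and RRN markers are flagged inapplicable.

Monte-Carlo percolation masks edges with i.i.d. Bernoulli(p) draws and
finds components with scipy's union-find-based sparse routine. All
stochastic cross-checks use three-standard-error bands with fixed seeds
and replicate counts (2000 for RRN-connectivity checks at generation ≤ 4,
400 per point for the collapse, 200 builds for the asymmetric ensemble
census at generation 3); these sizes keep the default suite within a few
minutes on one CPU while leaving the bands comfortably discriminating.
Diameters are exact all-sources BFS up to 3000 nodes and a double-sweep
plus 32-source lower bound beyond (observed exact on these hierarchical
graphs at the sizes tested); the empirical fractal dimension is the
least-squares slope of log N against log L over generations 3-6, where
the additive constant in the diameter recursion no longer biases the fit.

**Scaling collapse.** Order-parameter curves P_t(p, N_t) are sampled
inside each generation's scaling window p = p_c + x·N_t^{−1/ν̃} with
|x| ≤ 0.35, so every size probes the same scaling-function arguments; the
collapse quality is the mean squared vertical spread between rescaled
curves after interpolation onto the common abscissa range. Sampling far
outside the window instead lets corrections to scaling dominate the wings
(at these sizes they mimic a slightly lower effective β, defeating the
comparison against perturbed exponents). With the window choice, the
theory exponents beat every ±20% perturbation of (β, ν̃) by more than the
required factor of two.

## What the generators emulate, and limits

The built-in fixtures are the two symmetric 6-node/8-edge reference
generators (identical in every descriptor except triangle content — the
controlled comparison isolating the effect of clustering on robustness),
the asymmetric 5-node/7-edge reference, and the parametric cycle and
two-star families reproducing the classical flower and
Song-Havlin-Makse models. These produce exactly self-similar hierarchical
networks; real protein-interaction or contact networks are only
statistically self-similar, have noisy degree sequences, and are not
edge-transitive at any scale, so passing tests here validate the
renormalization machinery, not any claim about a particular empirical
network. Site percolation, average-path-length analytics, multigraph
generators (parallel root-root edges) and correlation measures beyond
assortativity and the Spearman coefficient are out of scope. Asymmetric
infinite-generation clustering and correlations have no closed form here
and are reported at the stated iteration tolerances; expected asymmetric
degree tables are dense in the degree, which caps the reachable
generation (about t ≤ 9 for root degrees 3 and 2).
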