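# Methods

## Graph construction

A fiber-bundle table holds one row per unordered ROI pair: streamline count
(≥ 1), mean fiber length (> 0, mm) and mean FA (∈ [0, 1]). Graph
construction deletes self-loop rows, rejects duplicate unordered pairs
(tables must be pre-aggregated per pair; silent merging would hide an
upstream aggregation ambiguity), keeps parcellation nodes without fibers as
isolated vertices, and drops edges whose weight evaluates to 0 (possible
only for `FAMean` with FA = 0), logging the count. Node order for all
matrix views is lexicographic in the ROI identifier, fixed at construction,
which makes every downstream computation — including solver tie-breaks —
deterministic.

Hemisphere scopes: `Left`/`Right` are induced subgraphs on the nodes with
that hemisphere label; midline/brainstem nodes are labelled `other` and
belong only to the `All` scope, which is the whole graph including
inter-hemispheric edges.

## Spectral and counting parameters

All eigenvalue work uses dense symmetric solvers (`numpy.linalg.eigvalsh`);
graphs have at most ~1000 nodes, where dense decomposition is both faster
and more robust than sparse iteration. One shared `SpectralSummary` per
(scope, weight) graph backs the four spectral parameters.

* **Transition eigengap.** The walk matrix **P** = **D**⁻¹**A** is
  non-symmetric; its spectrum is computed on the similar symmetric matrix
  **D**^(−1/2)**A** **D**^(−1/2). Degree-0 nodes get a self-transition of 1,
  preserving row-stochasticity; consequently any graph with an isolated
  node or more than one component has eigengap exactly 0, and the gap is
  clamped into [0, 2] against float spill at the single-edge extreme.
* **Spanning forests.** The weighted forest count is the product over
  connected components of the weighted matrix-tree value
  τ_w(C) = Σ_T Π_{e∈T} w(e). It is evaluated on the natural-log scale from
  the whole-graph Laplacian spectrum: drop the k smallest eigenvalues
  (k = number of components, detected combinatorially by BFS on the edge
  set, never by a spectral threshold), then
  ln τ = Σ ln λ_i − Σ_C ln |C|. The logarithm base is natural; magnitudes
  under weights < 1 can make the result negative. Positive weights make
  the true count strictly positive, so a non-positive numerical value is
  reported as −inf with a warning rather than silently propagated. The
  prose definition "sum of the logarithms of the weights of the spanning
  trees" circulating for this parameter conflicts with the matrix-tree
  method that computes it; this package implements the matrix-tree value
  log Σ_T Π w — the only quantity obtainable from the Laplacian spectrum.
* **AdjLMaxDivD** divides by the average degree over *all* n nodes
  (including isolated ones), 2·Sum/n. Edgeless graphs give NaN, as does the
  Hoffman bound (which needs λ_min < 0).

## Exact combinatorial solvers

The LP/MILP backend is HiGHS via `scipy.optimize.linprog`/`milp`, single
threaded, with required optimality gap 0; hitting the configurable time
limit (default 600 s per instance) raises an error carrying the best bound
rather than returning an approximate value.

* **Balanced minimum cut.** 0/1 program over side indicators y_v with
  Σ y_v = ⌈n/2⌉, continuous cut indicators z_e ≥ |y_u − y_v| and objective
  Σ w_e z_e; the lexicographically smallest node is fixed to side X
  (symmetry breaking, no loss of optimality). For small instances (up to
  ~200 000 candidate bisections, i.e. n ≤ 21) exhaustive vectorized
  enumeration is faster than the ILP and is selected automatically; both
  routes are exact and the ILP route can be forced, which is how the
  solver-vs-oracle tests keep two independent paths. The reported
  parameter divides the optimal cut weight by the total edge weight — the
  weighted `Sum`, reducing to the edge count in the unweighted case —
  making it invariant under uniform weight scaling.
* **Fractional vertex cover.** The published definition fixes the covering
  requirement at 1; the weighted variants reported alongside it are
  interpreted with the edge weight as the right-hand side
  (x_u + x_v ≥ w(u,v)), the extension consistent with the reported
  magnitudes (the FAMean optimum ≈ unweighted optimum × mean FA). This is
  an interpretive choice and is confined to this one parameter.
* **Binary vertex cover** is the classical ILP, unweighted scheme only.
  **Minimum spanning forest** uses Kruskal via networkx with edges
  pre-sorted lexicographically, so equal-weight ties resolve
  deterministically; it is rejected for the unweighted scheme, where every
  spanning forest has equal cost.

Brute-force oracles (exhaustive enumeration with explicit size caps:
bisection/cover n ≤ 16, spanning-tree enumeration n ≤ 8, half-integral
grid search for the fractional cover n ≤ 8) exist solely as independent
cross-checks in the test suite.

## Attribute table

120 attributes per resolution: {Sum, AdjLMaxDivD, PGEigengap, HoffmanBound,
LogSpanningForestN, MinCutBalDivSum, MinVertexCover} × 5 weights,
MinVertexCoverBinary × Unweighted, MinSpanningForest × the 4 weighted
schemes, each × {Left, Right, All}. Undefined values (edgeless scopes,
solver failures) are stored as NaN with a logged reason; a single
pathological graph never aborts a cohort run.

## Two-round statistics

The split by digit-sum parity of the subject ID is deterministic — no seed
is involved — and the two halves are independent samples. The two-group
ANOVA is implemented as the exact F(1, n−2) test, identical to the pooled
two-sample t-test (asserted to 1e-10 in tests). NaN attribute values are
dropped per attribute, never imputed; attributes constant across subjects
yield NaN p-values and are excluded from the family before ranking.

Holm–Bonferroni: the i-th smallest of the m surviving p-values is
multiplied by (m − i + 1). The default "paper" mode applies no running
maximum and no cap at 1 — the form used in the published reference table,
where corrected values above 1 appear; the "standard" mode (running
maximum, capped, as in statsmodels) is provided and recommended for new
analyses. Rejection uses the step-down rule (reject while
p_(i)·(m − i + 1) < α) in both modes, so the two modes always agree on the
rejection set. `significant_individual` flags p_round2 < α on its own;
`significant_family` flags membership in the Holm rejection set. The
family is formed jointly across all resolutions and scopes, as in the
reference table, and m is derived from the surviving set, never
hard-coded.

## Synthetic cohorts

The generator emulates the *statistical shape* the pipeline assumes, not
brain anatomy. Per subject and resolution: hemisphere-labelled nodes
(equal halves, odd remainder labelled `other`), independent edge sampling
at p_intra = 0.30 within a hemisphere and p_inter = 0.10 otherwise
(roughly the intra/inter density contrast of coarse connectomes), a
per-subject log-normal density multiplier with σ = 0.02 (mild
inter-individual variability), rounded log-normal fiber counts
(μ = 2.0, σ = 1.0 → median ≈ 7 streamlines), log-normal lengths
(μ = 3.4, σ = 0.5 → median ≈ 30 mm) and Beta(8, 12) FA (mean 0.4). Group A
(sex label F) carries multiplicative effects δ_p, δ_N, δ_FA on edge
probability, fiber count and FA; all default to 1, making the groups
exchangeable by construction. The δ_p = 1.05 used in the power analyses
mirrors the published f/m ≈ 1.05 unweighted edge-count ratio. Subject IDs
are consecutive 6-digit strings (100000, 100001, …), so the digit-parity
split is near-balanced and both halves contain both sexes.

Randomness: one root seed; each (subject, resolution) stream is derived
via `numpy.random.SeedSequence([seed, subject_index, resolution])`, so
cohorts are reproducible under any generation order and the group label
never enters the stream (exchangeability under the null is exact).

What the generator does **not** model: spatial embedding and
distance-dependent connectivity, tractography biases (e.g. premature
streamline stopping), correlated edges, heavy-tailed degree structure, or
resolution-dependent density. Passing calibration tests therefore shows
the *procedure* is valid and powered under the stated generative law, not
that real connectomes behave this way.

## Problem sizes and calibration checks

The statistical calibration runs 96-subject cohorts at the 129-node
resolution restricted to the cheap edge-sum family: 100 null replicates
bound the family-wise error (observed ≤ 8%, consistent with the 5% Holm
level plus Monte-Carlo noise), and 50 replicates with δ_p = 1.05 establish
≥ 90% power for detecting the edge-count effect. Full 120-attribute tables
(which include thousands of exact bisection and vertex-cover solves) are
exercised on 96-subject cohorts at five scaled-down resolutions of 8–16
nodes, and the analysis drivers use 16–24 nodes; at those sizes a 5%
density effect is below the binomial noise floor, which the driver reports
honestly and supplements with the 129-node edge-sum run. Solver-vs-oracle
equivalence uses 200 random graphs per problem at the oracle size caps.

## Known limitations

* The ILP bisection, while exact, has exponential worst-case time; graphs
  beyond a few hundred nodes with weak community structure may hit the
  time limit (and then error, by design, rather than approximate).
* The weighted fractional-cover right-hand side and the uncapped Holm
  variant reproduce the published convention; both have principled
  alternatives (requirement 1; capped monotone Holm) selectable in code.
* GraphML round-trips preserve isolated nodes; the edge-list CSV format
  cannot represent them.
* The published ranked reference table bundled under
  `braingraph/data/` renders 149 hypotheses whose corrected values imply
  one additional mid-ranked family member; the bundled arithmetic checks
  account for this with one multiplier step of slack (exact for the two
  top-ranked rows).
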