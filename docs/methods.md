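# Methods

`auxnet` analyses two-way, two-reporter yeast-2-hybrid (Y2H) screens of
interacting transcriptional regulators — the motivating system is the
auxin signalling network of *Arabidopsis thaliana*, where ARF activators
(ARF+), ARF repressors (ARF-) and Aux/IAA proteins dimerise through the
conserved C-terminal sub-domains DIII and DIV.  The pipeline turns the
raw screen into binary and valued interaction networks, clusters the
proteins with mixture models for random graphs, optionally regresses
edge weights on sequence-dissimilarity covariates, and assesses cluster
quality through connectivity-profile distances.

## Input model

Each ordered bait–prey pair carries one X-Gal mark on the 7-level
ordinal scale `- < -? < ? < +? < + < ++ < +++` and one HIS3
optical-density ratio (histidine-free over histidine-rich medium, ≥ 0,
possibly missing).  The schema holds a single value per ordered pair:
biological replicates are assumed to have been aggregated upstream, as
in the example tables this format mirrors.  HIS3 values written as
percentages (`119 %`) are divided by 100; no upper cap is enforced even
though observed ratios in the motivating screen stay below about 1.7.
Protein ids are normalized by stripping `AD-`/`BD-` orientation
prefixes, since orientation is already carried by the bait/prey columns.

## Binarisation

Reporter thresholds default to: X-Gal positive for marks ≥ `+` (the
boundary between `+?` and `+`), HIS3 positive for ratios ≥ 0.45, with
0.3 and 0.65 available as sensitivity presets.  The 0.45 default sits
near the boundary between the second and third components of a
three-component Gaussian mixture fitted to the pooled OD-ratio sample;
`fit_od_mixture` reproduces that analysis with unequal-variance EM
(20 restarts, tolerance 1e-8, BIC = log L − (p/2)·log n with p = 3K − 1
free parameters) and `component_boundaries` locates the points where
successive posterior probabilities are equal by root bracketing between
adjacent component means.  A missing HIS3 value scores negative
(conservative), as does a missing orientation (logged).

The four flags of an unordered pair (two reporters × two orientations)
map to decision configurations: 1 — all positive; 2 — exactly three
positive; 3 — one orientation positive for both reporters; 4 — one
reporter positive in each orientation; 5 — the same reporter positive in
both orientations; none — at most one positive.  Configurations 1–4
define an edge; configuration 5 is discarded as unreliable, so it and
"none" both yield absence.  Homodimer tests have a single orientation,
whose flags are used for both ways; the call is stored on the diagonal
and kept out of the block models.

## Rank standardization (valued network)

Both reporter outputs are reduced to mid-ranks over a single pooled
marginal per test (all observed ordered pairs, diagonal included):
Rank(v) = 1/2 + Σ_{u<v} f_u + f_v/2, the average-tie ranking.  HIS3 is
deliberately treated as ordinal: its response is saturating (close to
Michaelis–Menten kinetics), so only the order of ratios is trusted, and
mid-ranks handle exact ties the same way as the ordinal scale.  The
standardized distance of a pair is the weighted sum of the two tests'
normalized rank sums, with normalizer 1 + N² when both directed values
are present (so the mean over all N² ordered pairs is exactly 1).  With
a missing directed value the remaining rank is normalized by
(1 + M_test)/2, the direct symmetric extension of the one-missing-value
formula; when one test is missing in both orientations the weights are
renormalized over the available test, and a pair is flagged missing only
when every contributing value is absent.  Supported weightings
(w_XGal, w_HIS3): (1,0), A = (0.75,0.25), B = (0.5,0.5),
C = (0.25,0.75), (0,1).  The result is a likelihood-of-interaction
surrogate, not a binding constant.

## Block models and variational EM

Vertices belong to one of Q latent clusters with probabilities α_q;
conditionally on memberships, edges are independent with a law that
depends only on the endpoint clusters: Bernoulli(π_ql) for binary
graphs, N(μ_ql, σ²) for valued graphs, and
N(μ_ql + Y_ij'b_ql, σ²) for the regression family with d edge
covariates.  σ² is a single scalar shared across cluster pairs; μ, π
and every β component are symmetric in (q, l); the graph is undirected
with no self-loops, so all edge sums run over unordered pairs i < j.

The E-step uses the mean-field fixed point
τ_iq ∝ α_q Π_{j≠i} Π_l (φ_ij^{ql})^{τ_jl} in the log domain.  Rows are
updated **sequentially**: updating one row to the softmax of its field
is the exact coordinate-ascent maximizer of the bound J over that row,
so every sweep increases J and the oscillation that simultaneous
updates can produce cannot occur (no damping is needed).  Sweeps stop
when the largest elementwise change drops below 1e-6 or after 100
sweeps.  The M-step sets α to mean memberships and solves, for each
unordered cluster pair, the τ-weighted least-squares regression of edge
weights on covariates; σ² is pooled over all edges and cluster pairs.
Near-empty cluster pairs are stabilized with a ridge of 1e-10 times the
normal-equation trace.  EM alternates until the relative change of J
falls below 1e-8 or 500 iterations; the best of `n_restarts`
initializations wins, one from Ward clustering of the adjacency rows
(connectivity profiles) and the rest from random Dirichlet soft
memberships.  Fits are deterministic given `random_state`.

Model selection uses the ICL criterion with its double penalty —
(Q−1)/2·log n for the memberships attached to the n vertices and
Q²(d+1)/2·log(n(n−1)/2) for the edge parameters — giving
(Q−1) + Q²(d+1) independent parameters.  Scans report a posterior model
probability per Q as the exp-normalized ICL over the scanned models;
this softmax reading reproduces the behaviour that near-tied ICLs share
mass.  An ICL gap of at least log(100) ≈ 4.6 (Jeffreys' rule of thumb)
flags the best model as substantially better.  Reporting of regression
coefficients "significantly different from zero" is this package's own
convention: a nonparametric bootstrap over vertices (200 resamples, 95 %
interval excluding 0) can be layered on top of the fits; the core module
reports the raw coefficient matrices.

## Cluster-quality distances

D(i, j) = Σ_k |x_ik − x_jk| / N compares connectivity profiles; on a
binary matrix it is the Sokal–Michener mismatch proportion.  The k-sum
runs over all N columns including k ∈ {i, j}; diagonal adjacency entries
excluded from the model are imputed as 0.  Protein-to-cluster distances
use the soft membership weights and reduce, for deterministic
assignments, to denominators n_q − 1 (own cluster) and n_q (other
clusters); cluster-to-cluster, within- and between-cluster distances
follow with denominators n_q(n_q − 1), n_q·n_l and n_q(N − n_q).  All
accumulations use exactly rounded summation (`math.fsum`) so the hard
and soft formulas agree bitwise on 0/1 memberships; rosters are small
enough that this costs nothing.  Partition agreement between two
clusterings is the optimal-assignment match on the confusion matrix
(percentage rounded to integer).  Singleton or empty clusters yield
flagged NaN distances rather than failures.

## Synthetic data

The generator plants a block structure and emulates the screen's
statistical signatures: per orientation, X-Gal marks are drawn from
interaction-conditional ordinal distributions (interacting pairs over
`{+, ++, +++}` with probabilities 0.5/0.3/0.2; others over
`{-, -?, ?, +?}` with 0.55/0.2/0.15/0.1) and HIS3 ratios from a
three-component Gaussian mixture — components N(0.12, 0.05²),
N(0.30, 0.08²) below the 0.45 threshold (weights 0.7/0.3) and a broad
N(1.0, 0.25²) above it for interacting pairs — truncated so that a
noise-free screen binarizes back to the planted truth exactly.
Sign-flip noise and HIS3 missingness are applied at configurable rates
(defaults 0).  Covariate matrices are symmetric, zero-diagonal, with
within-/between-cluster means (defaults 0.3/1.0, jitter 0.3) truncated
at 0.  Default sizes mirror the motivating study: n = 46 for end-to-end
runs, with n ≤ 12 used where enumeration oracles must stay feasible.
What the generator does **not** emulate: replicate-level variation,
bait/prey-specific autoactivation artefacts, correlated noise between
the two reporters, and any real sequence evolution — so passing
recovery tests demonstrate correctness of the estimators under the
model's own assumptions, not robustness to every failure mode of real
screens.

## Problem sizes and numerical choices

Recovery benchmarks use n = 80, Q = 3, d = 2, σ = 0.05 regression
graphs and n = 60, Q = 3 Gaussian graphs with means 0.9 (within) and
0.3 (between), σ = 0.1 — strongly separated settings chosen so that the
true partition is identifiable and the variational posterior becomes
degenerate (every τ row within 1e-3 of a unit vector), as observed in
the motivating analysis.  ICL scans cover Q ∈ 1..6 with 3 restarts.
Exhaustive labeling enumeration (the EM oracle) is run at n = 8, Q = 2.
Probabilities are clipped at 1e-12 inside Bernoulli log-densities; the
shared variance is floored at 1e-12; 0·log 0 is taken as 0 throughout.

## Known limitations

* The Bernoulli family takes no covariates (no logistic link); directed
  and degree-corrected variants are out of scope.
* Missing valued-graph entries are imputed with the marginal mean value
  1 before fitting rather than being integrated out.
* The headline analysis of the motivating study depends on a raw screen
  table distributed in third-party supplementary material; the package
  reproduces the methodology and validates it on synthetic screens.
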