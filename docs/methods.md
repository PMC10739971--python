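# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. The package implements a four-stage pipeline —
manifold outline, supervised Bayesian projection, parametric 2-D embedding,
and quality metrics — plus seeded generators of manifold-structured
synthetic data.

## Manifold outline

**Model.** Samples are assumed to lie near a one-dimensional sweep of a
manifold in the target/output (or feature) space. Geodesic distances are
approximated by shortest paths over a symmetric k-nearest-neighbour graph
(union of directed k-NN relations, edges weighted by Euclidean distance;
`k_graph` defaults to 10). The *endpoint* is the sample maximizing the sum
of geodesic distances to all others, with ties broken toward the lowest
index — a deterministic extremal-point heuristic. One-dimensional scalar
sources are treated as a line manifold: distances are absolute differences
and the graph step is skipped.

**Binning.** The density of the (m²−m)/2 pairwise geodesic distances is
modeled as a zero-mean folded Gaussian; its scale is estimated by the
maximum-likelihood rule σ̂ = √(mean d²) over the pairwise distances. The
optimal equal-width histogram rule for that density gives
h\* = 12^(1/3) π^(1/6) σ̂ ((m²−m)/2)^(−1/3). That width is applied to the m
*endpoint* distances (the quantity the pipeline orders by): the density
model and pair count come from the pairwise sample, the binning from the
endpoint sweep. Bins span [min, max]; empty bins are dropped and survivors
renumbered 1..K in distance order, so every pseudo-label class is non-empty
(the projection requires this). A zero width or constant input collapses to
K = 1.

**Numerical choices.** Shortest paths use the Floyd–Warshall algorithm for
n ≤ 1500 and Dijkstra above (an O(n³) vs O(n² log n) size cutoff). The
graph representation keeps explicit zero-weight edges, so duplicate samples
always receive identical distances, colors and labels. Disconnected graphs
are repaired by repeatedly adding the single minimal Euclidean edge between
the two closest components, which leaves intra-component paths untouched.

## Supervised Bayesian projection

**Model.** With X feature-major (m × n) and pseudo-labels c ∈ {1..K}, the
generative model places gamma priors Φ (shape α_φ, scale β_φ) on the
precisions of the projection matrix Q (m × R), projects samples as
z_i ~ N(Qᵀx_i, I), scores classes through t_i ~ N(Wᵀz_i + b, I) truncated
to t_i^{c_i} > t_i^e (e ≠ c_i), and places gamma priors λ, Ψ on the
precisions of b and W. The mean-field posterior
q(Φ)q(Q)q(Z)q(λ)q(Ψ)q(b,W)q(T) is optimized by coordinate ascent in the
order Φ,Q → Z → λ,Ψ,(b,W) → T. All gamma factors use the (shape, scale)
convention; posterior updates add exactly 1/2 to each prior shape. The
joint (b_e, w_e) factor uses E[ZZᵀ] = Z̃Z̃ᵀ + n·cov_Z and the e-th column
of the score-mean matrix. The projected data is U = XᵀE[Q].

**Defaults and controls.** All six gamma parameters default to 1, R = 16,
at most 200 cycles. Convergence is declared when the max-norm relative
change of E[Q] falls below 1e-4. Initialization (the model is only
specified "randomly") is seeded: E[Q] ~ N(0, 0.01), E[Z] ~ N(0, 1),
E[b,W] ~ N(0, 0.01), covariances identity, and initial score means set to
the affine guess with a +1 margin on the own-class coordinate.

**Truncated-normal expectations.** E[t_i] is estimated from 200
standard-normal draws per sample per iteration (configurable), keeping
draws whose own-class coordinate is strictly maximal. Samples with no
accepted draw after 20 rounds fall back to their single best-margin draw —
bounded work, deterministic given the seed, never an exception. K = 1 is
handled exactly (the truncation is vacuous).

**Numerics.** Precision matrices get 1e-8 jitter before Cholesky
factorization; solves are symmetric, covariances resymmetrized. The Q
update forms an m × m covariance per component, so m is guarded at 2000;
higher-dimensional features must be pre-reduced by the caller (the error
says so). Features are z-scored by default (disable with a flag); the
fitted scaler is stored for out-of-sample projection.

**Behavior worth knowing.** Nothing in the likelihood rewards diversity
among the R components: when the class structure is effectively
one-dimensional (ordered bins along a sweep), the components converge
toward a common direction and U becomes near rank-1 — the embedding then
portrays the manifold ordering as a filament. This is a property of the
model, not a numerical failure; it is why the unsupervised swiss-roll study
(below) cannot out-score PCA on DEMaP.

## Manifold embedding

ρ_i is the distance to the first nearest neighbour; σ_i solves
Σ_j exp(−max(0, d_ij − ρ_i)/σ_i) = log₂(k) over the k nearest neighbours by
bisection (100 halvings after geometric bracketing; if every neighbour sits
exactly at ρ_i the equation has no solution and σ_i is set to the 1e-10
floor). d − ρ is clamped at 0 so p_{j|i} ≤ 1 keeps its probability reading.
Directed probabilities are symmetrized by probabilistic union. The map from
R-dim to 2-D is a single affine layer, initialized from the top-2 principal
directions of U scaled to unit spread, and trained with an in-package Adam
(β₁ = 0.9, β₂ = 0.999, lr 0.001, 200 epochs) on the cross-entropy loss with
q clamped to [1e-12, 1 − 1e-12]. For n ≤ 2000 the exact all-pairs loss and
gradient are used; above that, on-edge terms are exact and off-edge
repulsion is estimated by uniform pair sampling (`neg_samples` per directed
edge, rescaled to be unbiased for the exact loss). Training is
deterministic given the seed.

## Evaluation metrics

Geodesic-Pearson builds geodesic matrices in both spaces with the outline
module's construction (identical k_graph = 10 in both, by choice) and
correlates the upper triangles. DEMaP is the Spearman correlation between
high-dimensional geodesics and low-dimensional Euclidean distances. k-NN
accuracy uses 5 seeded stratified 70/30 train/test splits with a 5-NN
classifier — the stated interpretation of "5-fold, 70/30" reporting; both
fractions are honored. Constant distance vectors raise an error rather than
returning an undefined correlation.

## Synthetic data

`make_curve` draws t ~ Uniform(0,1) and lifts it through a random Fourier
series (3 frequencies, coefficients decaying as 1/frequency, columns scaled
to unit RMS) so `noise_sd` reads as a fraction of signal scale; the default
studies use n = 300, dim = 20, noise_sd = 0.05. `make_layer_features`
emulates a network layer: "trained" is a fresh smooth re-embedding of the
same latent parameter, "untrained" an independent Gaussian matrix of the
same shape. `make_blobs` places class means pairwise `sep` apart in units
of the unit within-class standard deviation. All generators are pure
functions of their arguments, seed included.

What the generators do *not* emulate: the sampling noise structure of real
network activations or read counts, batch effects, multi-branch or
higher-dimensional latent geometry, and class imbalance. Passing tests
therefore demonstrate correctness of the algorithms and recoverability
under the stated conditions, not performance on any particular real
dataset.

## Study sizes and reproducibility

The shipped studies use n = 300 for the supervised curve analyses, n = 400
for subspace recovery, and n = 1000 for the unsupervised swiss roll —
sizes at which every stage, including the exact-loss embedding and the
O(n³) shortest-path pass, completes in seconds to a few minutes on one
core. A single pipeline seed feeds independent derived streams for the
projection sampler and the embedding optimizer, so reruns are bit-identical
down to the written TSV artifacts.

## Known limitations

- The full pipeline map is affine in X (linear projection, single affine
  embedding layer): it orders samples along the manifold but cannot unroll
  curved manifolds the way free-point embeddings can. On the swiss roll its
  DEMaP consequently sits near the best-linear-fit ceiling of the
  endpoint-distance ordering — above the average random linear projection
  (though not every random draw) and below PCA, which simply preserves
  ambient variance.
- The outline assumes a single sweep with one endpoint; branching
  trajectories and multi-endpoint manifolds are out of scope.
- The m ≤ 2000 guard reflects the dense m × m covariance in the Q update;
  very high-dimensional features need prior reduction.
- Monte-Carlo score expectations add sampling noise to the coordinate
  ascent; with many classes the acceptance rate drops as 1/K and the
  estimates coarsen (mc_samples can be raised at linear cost).
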