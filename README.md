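# mda — manifold discovery and analysis

`mda` visualizes how high-dimensional data organize along a low-dimensional
manifold. It was designed for inspecting the hidden-layer features of trained
neural networks against the manifold of their targets — a well-trained layer
arranges its features along the target manifold, an untrained one does not —
and it applies equally to other data with a latent continuum, such as
single-cell expression profiles along a developmental trajectory.

## The method

Given a feature matrix **X** (m features × n samples) and optional
target/output vectors, the pipeline runs four stages:

1. **Manifold outline.** Pairwise Euclidean distances between the
   target/output vectors (or the features themselves, in unsupervised mode)
   are converted to geodesic distances over a k-nearest-neighbour graph.
   The sample maximizing total geodesic distance is taken as an endpoint of
   the manifold, and each sample's geodesic distance from it orders the data.
   Modeling the distance density as a zero-mean folded Gaussian
   p(d) = √2/(√π σ) exp(−d²/2σ²) gives a closed-form optimal histogram width

   h\* = 12^(1/3) π^(1/6) σ̂ ((m² − m)/2)^(−1/3),

   which bins the endpoint distances into K pseudo-labels c ∈ {1..K}.
   The normalized endpoint distance is the color scale of every plot.

2. **Supervised Bayesian projection.** A variational-Bayes model infers a
   projection **Q** (m × R) jointly with projected coordinates **Z**,
   per-class weights/bias (**W**, b) and gamma precisions (Φ, λ, Ψ).
   Truncated-normal score variables **T** enforce t_i^{c_i} > t_i^e for all
   e ≠ c_i, pulling samples that share a pseudo-label together, while the
   **XX**ᵀ term in the **Q** update preserves overall variance, PCA-style.
   The factors are updated by coordinate ascent (Φ,Q → Z → λ,Ψ,(b,W) → T;
   truncated-normal expectations by seeded rejection sampling) and the
   projected data is **U** = **X**ᵀE[**Q**].

3. **Manifold embedding.** A fuzzy neighbourhood graph over **U** assigns
   edge probabilities p_{j|i} = exp(−(d − ρ_i)/σ_i) to each point's k nearest
   neighbours (ρ_i the nearest-neighbour distance, σ_i calibrated so the
   smoothed neighbour count is log₂ k), symmetrized as
   p_ij = p_{j|i} + p_{i|j} − p_{j|i}p_{i|j}. A single affine layer mapping
   **U** to 2-D coordinates **V** is trained with Adam against the cross
   entropy between p_ij and the output kernel q_ij = (1 + a|v_i − v_j|^{2b})⁻¹.

4. **Evaluation.** Geodesic-Pearson (correlation of geodesic distances
   computed in both spaces), DEMaP (Spearman correlation of high-dimensional
   geodesics vs low-dimensional Euclidean distances) and k-NN classification
   accuracy over stratified 70/30 splits.

Defaults follow the method's standard settings: gamma scale parameters 1,
R = 16, 200 coordinate-ascent iterations, a = b = 1, k = 30 embedding
neighbours, Adam learning rate 0.001.

## Worked example

`examples/03_full_supervised_pipeline.py` lifts one latent curve into a
"trained" feature matrix (a smooth function of the latent parameter) and an
"untrained" one (independent noise of the same shape), then runs the full
pipeline on both:

```
trained   regime: geodesic-Pearson = 0.9873, DEMaP = 0.7633
untrained regime: geodesic-Pearson = 0.1457, DEMaP = 0.1305
```

The trained features embed into a continuous gradient whose geodesic
structure matches the data (correlation near 1); the untrained features
carry no manifold information and collapse toward 0. The other example
scripts cover the outline stage, the projection on its own, the
unsupervised mode, and the shell interface (`mda synth | outline | project |
embed | run | eval`).

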