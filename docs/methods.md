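# Methods

`shapeqtl` maps quantitative trait loci (QTLs) that control the outline of a
two-dimensional biological object — the motivating case is leaf silhouettes in
a cucurbit backcross — by treating an entire image as the phenotype. This
note records the model, the numerical choices, and what the simulations do
and do not establish.

## Model

**Design.** A backcross of n progeny, genotyped at M markers on a linkage
map; each locus carries genotype QQ (coded 1) or Qq (coded 2), segregating
1:1. Each progeny contributes one binary L×L silhouette.

**Pose removal.** Shape is the geometry left after location, scale and
rotation are removed, so each image i gets a pose p_i = [a, b, h, θ]
(x/y translation in pixels, isotropic scale, rotation) and the homogeneous
transform T[p] = M(a,b)·H(h)·R(θ) acting about the image center. All n
images are aligned jointly by steepest descent on the pairwise energy

    E = Σ_{i<j} Σ_Ω (Ĩ_i − Ĩ_j)² / Σ_Ω (Ĩ_i + Ĩ_j)²,

where Ĩ_i is image i resampled through T[p_i] (pull direction). The
normalization removes the degenerate minimum at h → 0 in which every shape
shrinks to nothing; an unnormalized variant is available
(`AlignConfig(normalized=False)`) for sensitivity checks. The first shape's
pose is pinned at the identity: the energy is invariant under one common
pose applied to all shapes, and the gauge must be fixed somewhere.

**Phenotype.** Each aligned silhouette is embedded as the zero level set of
a signed distance function (SDF): exact Euclidean distance between pixel
centers, negative inside, positive outside. Distances are pixel-center to
pixel-center, so foreground values are ≤ −1 and the zero contour lies
between pixels — this keeps the exact brute-force oracle meaningful and the
transform exact (`scipy.ndimage.distance_transform_edt`). Column-stacking
the SDF gives the phenotype row Y_i of length m = L².

**Mixture.** The unobserved QTL genotype makes Y_i a two-component mixture

    Y_i ~ ω_{1|i} N(μ₁, σ²I) + ω_{2|i} N(μ₂, σ²I),

with the weights ω_{j|i} the conditional probabilities of the QTL genotype
given the two flanking markers (standard no-interference backcross table;
Haldane map function, r = (1 − e^{−2d/100})/2). μ₁, μ₂ are unstructured
genotype mean fields; the residual covariance is σ²·I, shared by genotypes
and pixels — the simplest workable choice at m up to 65,536, and the one the
parameter-recovery tests validate. Structured mean or covariance models are
deliberately out of scope.

**Fitting.** Standard EM: the E-step is Bayes' rule over the two genotypes,
the M-step takes posterior-weighted means and the pooled posterior-weighted
mean squared deviation. All densities are handled in log space (log-sum-exp):
at m in the thousands the raw Gaussian densities underflow. Initialization is
deterministic — each progeny is hard-assigned to its likelier genotype by
ω — with one fallback restart from slightly perturbed means if a component
empties. Convergence: absolute log-likelihood change < 10⁻⁶, max 200
iterations.

**Testing.** At each position on a scan grid (default: every 1 cM plus all
markers; the replication experiments use 5 cM), LR = 2(ℓ_mix − ℓ₀) with ℓ₀
the closed-form single-component fit, computed once. To guarantee LR ≥ 0,
any EM fit that lands below ℓ₀ is refitted starting from the null solution
(μ₁ = μ₂ = μ₀), whose ascent can only improve on ℓ₀; running the null-start
only as a fallback rather than always halves the cost with the identical
guarantee. Genome-wide significance is the empirical (1−α) quantile
(type-7, linear interpolation) of max-LR over permutations that shuffle
whole phenotype rows against genotype rows. Defaults: 1000 permutations in
production, 100 in the replication tests, α = 0.05.

## Synthetic populations

The generator reproduces the study conditions: 200 progeny, one linkage
group of 11 equally spaced markers (10 cM spacing — the spacing is a
declared choice), QTL at the midpoint of the third interval (25 cM), and
phenotype fields Y_i = ξ_i μ₁ + (1 − ξ_i) μ₂ + e_i with e_i iid N(0, σ²)
per pixel and σ² = 1. Marker and QTL genotypes are drawn from one Markov
chain so ξ_i is exactly consistent with the flanking markers. Noise is
added in SDF space, where the additive multivariate-normal model is
coherent; the observable silhouette is the field thresholded at zero.

Genotype mean shapes are polar-boundary leaves,
ρ(φ) = r₀L(1 − δ·cos(kφ))(1 + s·cos 12φ) with y scaled by an elongation
factor: lobed and serrated for wild types, round for cultivars. Three named
presets fix the effect sizes: `big` (wild vs cultivar), `small-wild` and
`small-cultivar` (slightly different outlines within a type); a `null`
preset (identical means) supports calibration experiments. The paired
outlines of every preset have matched foreground areas: joint similarity
alignment removes per-shape size by construction, so a genotype effect
encoded as a size difference would be absorbed into the scale poses rather
than the genotype means. Encoding effects in pose-invariant features (lobe
depth, elongation, serration) is the coherent simulator design for a
pipeline whose first stage removes pose.

What the simulator does not emulate: digitization artifacts of real
photographs, within-genotype biological shape variation beyond iid pixel
noise (real residuals are spatially correlated), measurement-driven pose
variation at acquisition time (available separately via `perturb_poses`),
and multi-QTL or epistatic architectures. Passing tests therefore show
correctness of the machinery and power under the stated additive model, not
performance on photographic data.

## Numerical choices

- **Alignment differentiability.** Binary images have no spatial gradient,
  so each image is pre-smoothed with a Gaussian (σ = 1 px) for
  optimization. During descent images are represented by an interpolating
  bicubic spline of the smoothed image: the spline's coordinate derivatives
  are exact, so the analytic pose gradient (chain rule through the
  transform Jacobian) agrees with finite differences to ~10⁻⁹ relative
  error. Final aligned images are bilinear resamples of the *original*
  binary image; nearest-neighbor sampling is available for visualization.
- **Descent.** Steepest descent with backtracking line search (initial step
  0.1, shrink 0.5, modest re-growth after acceptance), tolerance 10⁻⁶ on
  relative energy change, max 500 iterations. One step size serves all
  components because translations are in pixels, scale is optimized as
  log h (which also enforces h > 0), and rotation in radians. Warm start
  from foreground centroids and areas.
- **Distance transform.** Exact EDT, not chamfer: phenotype values enter a
  likelihood, and approximation error would contaminate the
  parameter-recovery checks.
- **Variance floor.** σ² is floored at 10⁻¹² so degenerate inputs (identical
  rows) cannot produce log(0).
- **Degenerate scan positions.** Where every progeny shares one flanking
  genotype, a mixture component receives no posterior mass; the batched
  fitter keeps that component's previous mean (its likelihood contribution
  is zero), so such positions reduce gracefully to the null fit and LR ≈ 0.
- **Batched permutation EM.** Permutation scans fit all permuted weight
  matrices simultaneously per position with matrix products against the one
  shared phenotype matrix; a consistency test pins the batched path to the
  reference per-dataset EM. Shuffling phenotype rows is implemented as
  permuting weight rows, which avoids copying the phenotype matrix.

## Problem sizes used in the replication experiments

The shipped experiments run the simulated designs at L = 32 (replications)
and L = 16 (calibration) rather than the original 75×75 grid, with 100
permutations and 20 replicate seeds; these sizes keep the full suite quick
on a laptop while leaving every statistical conclusion intact, since power
at L = 32 is if anything lower than at L = 75 (fewer informative boundary
pixels). `scripts/acceptance.py` exposes `--grid-size`/`--n-perm` to rerun
at other scales.

## Known limitations

- A strongly bimodal phenotype lets the mixture re-find the two clusters
  under permutation (the fit exploits soft weights at interior positions),
  so permutation thresholds sit close below the observed peak when the QTL
  effect is huge; detection then rests on the linkage information in the
  weights, which is exactly what distinguishes the true position. The test
  remains calibrated under the null (verified empirically).
- Per-shape similarity alignment absorbs any genotype size effect; size
  must be analyzed separately if it matters.
- Joint alignment is a local method: grossly rotated inputs (beyond ~±30°)
  can converge to a lobe-permuted optimum for rotationally symmetric
  shapes.
- Missing marker genotypes and non-backcross designs are not supported.
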