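# Methods

This note documents the models, estimators and numerical choices behind
`spinemorph`, in the spirit of a package reference: what is computed, under
which assumptions, with which defaults, and what the synthetic benchmarks
do and do not demonstrate.

## Synthetic benchmark model

Real labeled spine datasets provide no ground truth for geometry or for the
continuum position of a spine, so every quantitative contract in this
package is validated on synthetic data with known generating parameters.

**Feature-space generator.** Each of the three archetypes (mushroom,
stubby, thin) is a Gaussian in a 12-dimensional feature space whose means
are morphologically plausible (e.g. mushroom: head diameter 24 px, neck
length 8 px; thin: head diameter 8 px, neck length 20 px; stubby: neck
length ≈ 0 — stubby spines lack a distinct neck). Per-feature standard
deviations are 10% of the cross-archetype range, which puts archetypes
roughly 4–6 noise SDs apart: separated enough that a nearest-centroid rule
recovers ≥ 95% of labels, close enough that k-NN graphs mix at borders.
A `mixing_fraction` share of rows (default 0.2) is drawn around a point on
the segment between an archetype mean and a transition partner at latent
coordinate t ~ U(0, 0.5); partners follow the biologically common routes
(mushroom↔stubby, mushroom↔thin — thin and stubby remodel via the mushroom
form, not directly into each other). This is the package's idealization of
the morphological continuum: linear in feature space, pairwise between
archetypes. Class counts default to the naturally observed imbalance
3:2:1 (mushroom:stubby:thin).

**Image generator.** A spine silhouette is an ellipse head (axis ratio
0.9), a rectangle neck and a half-disc shaft junction, rotated analytically
(membership functions evaluated at rotated coordinates, so no interpolation
artifacts). Intensity is region-wise constant (head 1.0, neck/shaft 0.75)
before a Gaussian PSF blur (default σ = 1.5 px) and additive Gaussian noise
(default sd 0.05); the mask is the exact pre-blur silhouette. Crops default
to 128 px at 0.05 μm/px. Geometry parameters are jittered ±10% per spine
(orientation ±0.3 rad) and stored as per-crop ground truth. No quantitative
PSF/noise parameters are claimed for any real microscope; the defaults are
chosen so that feature extraction is accurate on clean crops and visibly
degraded on corrupted ones.

**Degradation preset.** The low-resolution condition block-averages
intensities by a factor of 2 and adds Gaussian noise of sd 0.5 (≈ unit-SNR
for unit-peak images); masks are downsampled by majority vote with ties
kept as foreground, which preserves 2-px-wide thin necks. A factor-8
downsample (mirroring the 1024→128 px contrast between the two acquisition
protocols the framework is aimed at) is supported and tested, but at the
128-px desk scale it collapses thin-spine masks below the 8-px morphometry
floor, so the study preset uses the milder factor with heavier noise to
reach the same regime of feature-level corruption.

**What passing tests do not show.** The generator has no dendrite shaft
clutter, no anisotropic PSF, no photon (Poisson) noise by default, no
projection-angle variation, and its continuum is linear. Results on it
demonstrate correctness of the estimators and the directional behavior of
the decision logic, not performance on real 2PLSM data.

## Morphometry

Masks are reduced to their largest connected component; masks under 8 px
are rejected as degenerate. Lengths are reported in μm via `pixel_size`.

- **Perimeter** is the length of a marching-squares contour simplified to a
  polygon (tolerance 1.2 px). Pixel-edge perimeters overestimate staircase
  boundaries in a resolution-dependent way; the polygonal estimate keeps
  circularity within ~1% of the ideal for a rasterized disc and scale-free
  descriptors within 10% under 2× nearest-neighbor resampling.
- **Neck/head geometry** is fully automatic: head radius = maximum of the
  Euclidean distance transform (largest inscribed disc); the spine axis is
  the geodesic path through the 8-connected skeleton graph from the
  skeleton point nearest the head center to the farthest skeleton point.
  The terminal spur where the skeleton dives toward a boundary corner
  (monotone EDT descent at the attachment end) is trimmed; the neck is then
  delimited on the EDT profile along the axis — it starts where the axis
  leaves the head disc and ends where the profile, having passed its waist,
  rises a quarter of the way back toward its downstream peak (the
  attachment flaring out again). Neck width is twice the waist value. On
  unjittered synthetic crops these estimates land within 15% of the
  generator's ground truth (stubby necks ≤ 2 px); they are heuristics, not
  segmentations, and are validated only against the generator.
- **Texture** uses a mask-restricted GLCM (16 gray levels min–max quantized
  over the masked intensities, distance 1, offsets 0°/45°/90°/135°,
  symmetrized and normalized per offset) — only pixel pairs with both ends
  in the mask are counted, so background never contaminates co-occurrence.
  GLCM correlation falls back to 0 for (near-)constant patches. HOG uses 9
  orientations and 8×8 cells on the zero-padded bounding box and is
  summarized by descriptor moments, since a fixed-length descriptor is not
  needed downstream.
- **Screening** reports raw two-sided Mann–Whitney U p-values per feature
  and class pair (α = 0.05 by default, Benjamini–Hochberg available but
  off, matching common practice of reporting uncorrected pairwise screens);
  a feature failing α in *all* pairs is non-discriminative. Redundancy is
  greedy: features are visited in order of increasing minimum p-value and
  dropped if |Pearson r| ≥ 0.9 with an already-kept feature. The contour
  family intentionally carries solidity and the convex-hull ratio as an
  identical pair (both are A/convex area under the definitions used); the
  screen removes one, which doubles as a built-in self-test.

## Embedding harness and PCUMAP

All five methods consume the z-scored feature table; high-dimensional
distances are Euclidean on that table throughout, so every method is scored
on the same basis. Defaults: 3 output dimensions, 15 neighbors
(UMAP/ISOMAP), perplexity 30 (t-SNE), all clamped to the sample size;
every stochastic method takes an explicit seed and is bitwise reproducible.

PCUMAP is implemented as a post-hoc refinement of a fitted UMAP embedding
(the one-line description of the original — UMAP plus a correlation-based
global objective — leaves the integration unspecified, and a post-hoc
ascent makes the "identity at zero iterations" contract exact). The
objective

    J(Z) = λ · pearson(d_high, d_low(Z)) − a · mean‖Z − Z₀‖² / s₀

uses the analytic gradient of the Pearson correlation between condensed
distance vectors; s₀ (mean squared spread of the base embedding) makes the
anchor penalty scale-free. Ascent uses normalized gradient steps with
backtracking (halving, 20 tries) so accepted steps never decrease J;
defaults λ = 1, a = 0.5, 150 iterations, initial step 0.05·√s₀. The
anchor keeps points near their UMAP positions, which is what preserves the
base k-NN structure; the final k-NN overlap with the base is recorded.

## Structure metrics

Trustworthiness and LCMC implement the textbook formulas directly
(T(k) = 1 − 2/(nk(2n−3k−1)) Σᵢ Σ_{j∈𝒩ᵢ^embed} max(0, r(i,j) − k), with
ranks computed in the original space; LCMC = (1/kn) Σ|𝒩ᵢ^orig ∩ 𝒩ᵢ^embed|
with no adjustment term). k defaults to 10; neighbor ties are broken by
index for reproducibility. LS, GS and SPS are the exact linear identities
given in the README; reported values are rounded half-away-from-zero to
3 decimals, raw values are kept alongside for selection.

**BTS.** Natural logarithm (no base is implied by the formula); the
neighbor count defaults to the same k = 10 as the local metrics; distances
are floored at ε = 1e-6 before 1/log(d+1) (the kernel diverges as d→0),
and the number of floored pairs is recorded — with cosine distances on
nearly-collinear embedded points the floor dominates and BTS is then only
meaningful comparatively, which is its intended use. A zero denominator
(every neighbor pair carries weight 0, e.g. only thin↔stubby pairs under
the default scheme) raises an explicit `UndefinedBTSError` rather than
returning a value. Weight schemes are validated: symmetric, entries in
[0,1], diagonal maximal.

**KDE overlap (AO).** Per class pair, the overlap coefficient ∫min(p,q) of
Gaussian KDEs (Scott's rule, fitted in the full embedding dimension) is
estimated by importance-corrected Monte Carlo: 10,000 draws from the
mixture g = (p+q)/2, averaging min(p,q)/g. This is unbiased for the
integral and agrees with dense-grid integration within 0.02 on 2D
Gaussian test cases. AO is the mean over pairs.

## Clustering

**Ward** uses the agglomerative merge criterion
D(A,B) = |A||B|/(|A|+|B|)·‖μ_A−μ_B‖² on Euclidean coordinates; merge costs
are recovered from the linkage heights h as D = h²/2 and exposed for
inspection. **FCM** (fuzzifier m = 2, tolerance 1e-6 on max|Δu|, Dirichlet
random initialization) alternates exact centroid and membership updates;
points coinciding with centroids split membership equally among the
zero-distance clusters; the objective J_m is recorded per iteration and is
non-increasing by construction of the alternating minimization.
**GMM** is fitted by EM (full or diagonal covariance, 1e-6·I
regularization, best of 5 seeded initializations, each started from K
sampled points plus one hard assignment step); the log-likelihood trace is
recorded and non-decreasing. Non-convergence is reported via a flag, never
an exception; initializations with singular covariances are discarded.

**Hard validity** (silhouette, Davies–Bouldin, Calinski–Harabasz) is
computed from the defining formulas on explicitly differenced distances.
Dot-product distance shortcuts (‖x‖²+‖y‖²−2x·y) differ from naive
differencing at ~1e-8 relative, which matters because these implementations
are contract-tested against brute-force oracles at 1e-9. Conventions:
singleton clusters contribute silhouette 0; C-H returns 0 when the
between-cluster dispersion vanishes (coincident data). **Soft validity**
uses natural logs with 0·log 0 ≡ 0.

**Cluster-number selection.** The K grid defaults to 2–10. Candidates: the
first silhouette peak (smallest K beating both grid neighbors, one-sided at
the ends), the Davies–Bouldin minimum, and the CHull elbow — implemented as
the scree-ratio test on the upper convex hull of (K, −distortion) points,
where distortion is the within-cluster sum of squared distances to
centroids: hull points maximize the ratio of incoming to outgoing slope.
Decision rule: take the elbow when it lies between the other two candidates
(inclusive, order-free); otherwise the median of the three. The rule is
deterministic and its inputs (full curves, all three candidates, a
rationale string) are always reported, because on continuum-structured data
the criteria legitimately disagree.

## Transition analyses

Connectivity counts each spine's k = 10 Euclidean nearest neighbors by
(own cluster, neighbor cluster), normalizes to total mass 1, and
symmetrizes by averaging directional counts. Ambiguous spines are those
with maximum membership < 0.60; Cohen's d uses the pooled-SD definition
with the (n₁+n₂−2) denominator; empty groups yield flagged-undefined
effect sizes, not exceptions. Cross-partition agreement uses the adjusted
Rand index. The balanced-subset rerun subsamples every class to the
smallest class count (seeded) and repeats embedding + clustering, reporting
cluster-size dispersion and contingency before and after.

## Decision stages

Stage A selects the embedding with the highest SPS; when several methods
sit within 0.005 SPS the Euclidean BTS decides (the tie band is an artifact
constant: "most balanced" needed a numeric rule, and 0.005 is one rounding
unit at the 3-decimal reporting precision). Methods that fail to fit or to
score are recorded as failures and the stage continues while at least one
survives. Stage B selects the clustering method by best silhouette at the
chosen K; soft metrics are reported but not scored, and Ward's soft fields
are marked not-applicable. Reports embed the full configuration, its hash
and the package version; timestamps live in a separate field so content is
bit-reproducible under a fixed seed.

## Problem sizes used in the shipped studies

The packaged preset runs 300 spines (150/100/50) for feature-space studies
and 120 crops of 128 px for image-based studies, with 10 replicates in the
degradation comparison; metric-oracle batteries use 200 random instances
with n ≤ 40. These sizes were chosen so the full validation suite runs on
a laptop-class single core in a few minutes while keeping every statistical
check comfortably powered.

## Known limitations

- Geometry heuristics assume a single spine per crop with one dominant
  head; double-headed or branched spines are out of scope.
- The exact 35-feature list of the original SpineJ-based collection is not
  published in full; the families and counts match, member-for-member
  parity is unverifiable.
- Per-method embedding hyperparameters beyond the defaults above are not
  reproduced from the original study (unavailable); they are declared
  package defaults.
- BTS magnitudes are scale-dependent across embeddings; only comparisons
  under a fixed distance metric are meaningful.
- The CHull elbow is computed on the distortion curve of hard labels; for
  soft methods this ignores membership spread (the soft metrics report it
  separately).
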