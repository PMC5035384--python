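# Methods

This note documents the statistical procedures, numerical conventions
and design choices behind `morphsel`, and what the synthetic-data
generator does and does not emulate.

## Shape quantification

**Generalized Procrustes alignment.** Configurations are centred,
scaled to unit centroid size, and iteratively rotated onto the running
consensus by the closed-form 2-D least-squares rotation, restricted to
proper rotations (specimens are assumed digitized in a consistent
orientation, so reflections would only mask digitizing errors).
Convergence: relative consensus change < 1e-8, cap 100 iterations; a
failure to converge raises, reporting the last change. Output
convention: the consensus is the mean of the aligned configurations,
and all configurations share one final rescale putting the consensus
at exactly unit centroid size — so "mean of aligned = consensus" and
"consensus CS = 1" both hold exactly, while individual specimen CS
sits within O(shape variance) of 1.

**Semilandmark sliding.** When a slider table is supplied, each
semilandmark may slide along the chord joining its two declared
neighbours (the common chord/tangent approximation; outline endpoints
use whatever neighbours the slider file declares, which for an open
curve means a one-sided chord). The slide amounts per specimen jointly
minimize the thin-plate-spline bending energy of the deformation from
the consensus, a linear solve in the bending-energy quadratic form
(the upper-left block of the inverse TPS system matrix, kernel
`U(r) = r² log r²`). Sliding and re-superimposition alternate for up
to 5 cycles or until the consensus moves < 1e-6. Sliding minimizes
bending energy, not Procrustes distance — the default of the standard
relative-warp tools.

**Relative warps.** Computed as principal components of the aligned
coordinates about the consensus, i.e. weighting exponent α = 0 with
the uniform (affine) component included — the only convention under
which relative warps coincide with PCA of the superimposed
coordinates. Before the decomposition the coordinates are projected
into the shape tangent space at the consensus (removing the four
similarity directions: two translations, infinitesimal rotation,
scaling). Superimposition alone leaves second-order leakage in those
directions because aligned shapes live on a curved manifold; the
projection removes < 0.1% of the variance but makes the dimension
count exact: k 2-D landmarks yield 2k − 4 non-degenerate components
(54 for k = 29). Component signs are fixed by making each loading's
largest-magnitude entry positive; eigenvalues use the n − 1
denominator.

**Retention rule.** Downstream analyses keep the smallest number of
leading warps whose cumulative percent variance exceeds 80%.

## Selection analysis

**Standardization and relative fitness.** Traits are standardized to
mean 0, variance 1 with the sample (n − 1) standard deviation; fitness
is divided by its episode mean. Both are done within episode, once, on
the full episode sample, before any permutation.

**Gradients.** β comes from the first-order OLS regression of w on
the standardized traits; γ from the full second-order model (all
linear, squared and pairwise-product terms fitted jointly), with
squared-term coefficients doubled onto the diagonal, matching the
`w = a + β'z + ½ z'γz` surface convention. OLS is used even for
binary mating fitness — the estimands of this framework are
least-squares projections of relative fitness, and a logistic fit
(available as `selection.logistic_diagnostic`) is a diagnostic only,
never the reported gradient.

**Permutation inference.** Fitness values are shuffled across
individuals; the design matrix is fixed, so each replicate's
coefficients are one matrix product with a precomputed pseudoinverse
(9999 permutations of a 500 × 21 design cost well under a second).
Two-tailed p per coefficient:
`min(1, 2·min(r_le + 1, r_ge + 1)/(N + 1))`, where r_le/r_ge count
pseudo-estimates at or below/above the observed one; the add-one
correction keeps p > 0 and makes the test valid at finite N. Separate
randomizations are run for the first- and second-order models.

**Canonical analysis.** γ is diagonalized (eigenvalues sorted
descending, eigenvector signs fixed as above); θ_i and a
regression-based λ_i are re-estimated by "double regression": w on the
canonical scores y = zM' and their squares, with no cross-products of
distinct canonical axes (γ is diagonal in this frame by construction,
and the omitted terms have zero population coefficients for an exactly
quadratic surface — the identity λ_reg = eig(γ̂) is verified to 1e-6
in the tests for that case). θ is reported from this joint fit rather
than as the projection Mβ; the two differ whenever the linear
coefficients of the first- and second-order models differ.

**Eigenvalue permutation test — rank matching.** Each permutation
replicate refits the full second-order model, rebuilds and
re-diagonalizes its own γ, and contributes its *ordered* eigenvalues;
the observed i-th ranked eigenvalue is referred to the permutation
distribution of i-th ranked eigenvalues (and similarly the rotated
linear gradients for θ). Rank matching is essential for size: the
extreme eigenvalues of an estimated γ are extreme order statistics
even when fitness is independent of all traits, so a procedure that
holds the observed rotation fixed and compares the observed extreme
eigenvalue with fixed-axis permuted coefficients rejects the trailing
axis at ~60% under the null (measured at n = 500, 999 permutations).
The rank-matched version holds the 5% level on every axis in the same
simulation and retains full power against a planted λ = −0.5 axis.
This was a genuinely open design point and the measured size decided
it.

**Episode comparison.** Observations from the two episodes (each
standardized and relativized within episode) are pooled with an
episode indicator, and episode × term interactions are tested in
cumulative blocks — linear; then quadratic with the linear
interactions retained; then correlational with both retained — via
partial *F*: `F = [(SSE_red − SSE_full)/Δdf] / [SSE_full/df_full]`,
with parametric F p-values. With pooled n and p traits the
denominator dfs are n − (2 + 2p), n − (2 + 4p), n − (2 + 4p + p(p−1)):
996, 986, 966 at n = 1008, p = 5. Per-trait quadratic differences come
from single-interaction-term deletion out of the quadratic-block full
model (F with 1 numerator df). The block F is invariant to swapping
episode labels.

**Fitness surfaces.** Penalized thin-plate splines of w over two
predictors (typically two canonical axes), solving
`(K + nλI)c + Pd = w, P'c = 0` via a null-space QR reduction and one
eigendecomposition, so the whole smoothing path costs a single O(m³)
factorization. The smoothing parameter minimizes
`GCV(λ) = n·RSS/(n − tr H)²` over 40 log-spaced candidates spanning
1e−6 to 1e3 times the mean penalized eigenvalue (a data-scale
normalization). λ = 0 interpolates exactly; λ → ∞ recovers the
least-squares plane. Duplicate predictor points are collapsed to
their multiplicity-weighted mean fitness before fitting. The surfaces
are descriptive; no inference is attached to them.

**Repeatability.** One-way ANOVA intraclass correlation
`R = (MSB − MSW)/(MSB + (m − 1)MSW)` for balanced designs, with the
exact F-distribution 95% interval
(`FL = F/F_{1−α/2; n−1, n(m−1)}`, `FU = F·F_{1−α/2; n(m−1), n−1}`,
bounds `(F* − 1)/(F* + m − 1)`). Negative point estimates are reported
as computed: the variance-component estimator is unbiased and
truncation would not be. Simulated coverage at R = 0.75 (200 subjects
× 2 measurements) is within 3 percentage points of nominal over 500
replicates.

## The synthetic-data generator

The generator emulates the two-episode study design so that the whole
pipeline can be exercised with known truth:

- **Outlines**: a smooth open 29-point curve (3 fixed landmarks at
  positions 1, 16, 17; 26 semilandmarks), deformed along three planted
  axes that are orthonormal and orthogonal to the similarity group of
  the consensus (so alignment cannot absorb them), scaled by a
  lognormal specimen size (log-SD 0.05), plus isotropic digitizing
  noise (SD 0.002 in consensus units). Axis SDs (0.030, 0.0125,
  0.0096) put roughly 65/11/7% of shape variance on the three axes
  over the noise floor, mirroring the emulated study's spectrum.
- **Body size**: pronotum width ~ N(1.25, 0.05²) (mm scale),
  correlated 0.2 with log genital size — genital size is only weakly
  condition-dependent in the emulated system.
- **Fitness surface**: η = β'z + ½z'γz on the standardized true
  traits. Defaults for β and γ are the published mating-episode
  estimates, so the default synthetic study has the emulated study's
  selection structure (stabilizing, with correlational terms and
  well-separated eigenvalues).
- **Mating episode**: 500 trials; success ~ Bernoulli(logistic(a + η))
  with the intercept solved numerically so the expected rate is 0.49
  (245/500).
- **Fertilization episode**: 508 trials; structural zeros with
  probability 0.20 ("one-fifth of mated females produce no
  offspring"), positive counts 1 + negative-binomial (dispersion 1.5,
  base mean 18, mean exp-linked to η) clipped into 1–80. The zero
  fraction and range are design targets; the distribution between
  them is a declared stand-in, as the emulated design reports nothing
  more specific.
- **Two-digitization mode** adds independent landmark noise twice to
  the same underlying outline for repeatability studies.

**Implied gradients.** The generator's β/γ live on the link scale
(logistic or log), but the Lande–Arnold estimand is the least-squares
gradient of expected *relative* fitness, which the link attenuates
and warps (a logistic link at a 49% rate roughly halves γ).
`simulate.implied_gradients` therefore computes the population
gradients the pipeline should recover, independently of any study
sample: a large trait draw with the generating correlation structure,
the noiseless conditional-mean fitness at each point, and its
projection onto the first- and second-order designs. End-to-end
recovery is judged against these implied values; comparing against
the nominal link-scale coefficients would conflate link curvature
with estimation error.

**What passing recovery does and does not show.** The generator's
shapes are low-rank plus isotropic noise and its traits are
(log-)normal; real outlines have richer covariance, outliers and
non-normal size distributions, and real digitizing error is not
isotropic. Recovery at n = 5000 demonstrates that the pipeline's
estimators are consistent and correctly wired, not that selection
estimates from ~500 real specimens carry comparable precision — at
the study's own sizes the permutation tests, not the point estimates,
carry the inference.

## Problem sizes in the validation suite

The test suite runs the null-calibration studies at 500 replicates
with n = 500 and 999 permutations, ICC coverage at 500 replicates of
200 × 2, and the end-to-end recovery at n = 5000 — sizes at which the
binomial bands and 3-SE criteria are informative while the whole
suite completes in a few minutes on one core. The acceptance script
uses the study-design sample sizes (500/508) for the pipeline pass
and n = 5000 for recovery.

## Known limitations

- 2-D landmarks only; no 3-D morphometrics and no curve resampling
  from images (digitization itself is upstream of this package).
- Semilandmark sliding uses chord tangents; no spline-based tangent
  estimation.
- Exactly two episodes in the sequential comparison; no mixed-model
  or more-than-two-episode extensions.
- The published fertilization-episode γ carried in
  `morphsel.datasets` contains an entry (γ(RW1, PW) = −1.533) that is
  inconsistent with the published eigenvalues for that episode (the
  trace matches; the full decomposition cannot, and back-solving
  suggests ≈ −0.07). It is provided as printed and flagged; the
  mating-episode matrix is the worked-example eigendecomposition
  check.
- Selection differentials, mean-standardized gradients and Bayesian
  gradient estimation are out of scope.
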