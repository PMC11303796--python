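# Methods

This note records the models implemented in tractoflux, the defaults and
why they were chosen, the numerical decisions, and what the synthetic data
do and do not establish.

## Multi-compartment signal model

A voxel's attenuation is `α exp(−b d_iso) + Σ_j β_j exp(−b gᵀ D_j g)` with
`α + Σ β_j = 1`. The isotropic compartment is free water with fixed
diffusivity `d_iso = 3.0e-3 mm²/s`; estimating it (or adding a second
isotropic pool) is deliberately not supported — one fixed free-water term
is the stable choice at clinical SNR. Anisotropic compartments are
zeppelins: axially symmetric tensors with eigenvalues (λ∥, λ⊥, λ⊥), which
model one coherent fiber population each; up to three per voxel cover
straight tracts and 2- or 3-way crossings.

Bounds keep the optimizer in physiological territory: λ∥ ∈ [0.1e-3,
3.0e-3] mm²/s and λ⊥ ∈ [0.01e-3, λ∥] (parameterized as a fraction of λ∥ so
the prolate constraint is structural). Mixture weights go through a softmax
with the free-water logit pinned at zero, so the simplex constraint is
exact by construction and verified to 1e-9 after every fit. Axes are stored
with non-negative z (zeppelins are antipodally symmetric) and compartments
ordered by descending weight, so fits are canonical and comparable.

### Likelihood and the Rician floor

Estimation is maximum likelihood under Gaussian noise, i.e. nonlinear least
squares (scipy `least_squares`, trust-region reflective with box bounds).
The fitted forward model is, by default, the *expected Rician magnitude*
`E[M] = σ √(π/2) · L_½(−ν²/2σ²)` of the noise-free attenuation ν, with the
noise floor σ estimated jointly (one extra parameter, shared across all
measurements; `FitConfig(rician_mean=False)` reverts to fitting ν itself).
The reason is quantitative: magnitude data at b = 3000 s/mm² sit near the
noise floor, and fitting the noise-free mean there leaves a systematic
residual that an extra spurious compartment can absorb. In simulation the
likelihood-ratio of an extra compartment on single-fiber data was inflated
(−2Δlog L averaged 8.8 against the χ²₅ reference mean of 5), which cost
about 16% of model-selection decisions at SNR 50; with the expected-
magnitude fit the statistic is calibrated and selection accuracy is ~96%.
The Laguerre function is evaluated through scipy's `hyp1f1`, which is
stable over the whole SNR range. At σ = 0 the correction vanishes, so
noise-free identities are unaffected.

Multi-start: each candidate model is fitted from `n_starts` (default 5)
initializations — one data-driven (axes at the most-attenuated gradient
directions, mutually separated by ≥ 30°) plus seeded random axis sets —
and the best residual wins. Diffusivities start at (1.7e-3, ~0.35e-3)
mm²/s, typical white-matter values.

### Model selection

All candidate compartment counts n = 0..3 are fitted and scored by AICc
with the Gaussian noise variance profiled out; the parameter count is
5n + 2 (n mixing logits, 4 geometry/diffusivity parameters per zeppelin,
the profiled variance, the Rician floor). Akaike weights are exposed for
audit and optional metric averaging (`average_metrics=True`); the default
output is the single highest-weight (lowest-AICc) model, ties to fewer
compartments. On noise-free data every adequate model reaches a residual
of numerically zero, so the residual sum of squares is floored at
1e-12 per observation before taking logs; candidates that fit equally well
then compare purely by parameter count, which makes the noise-free
selection identities exact rather than dependent on which optimizer run
got closer to machine zero.

## Tractometry

Streamlines are resampled to equal arc-length spacing (linear
interpolation along the cumulative chord length). The minimum-direct-flip
(MDF) distance between two streamlines resampled to n points is the mean
pointwise Euclidean distance minimized over reversing one of them; it is
symmetric and satisfies the triangle inequality on orientation classes.

A bundle's centroid is the pointwise mean of its streamlines after
resampling each to s points (default 100) and flipping it, when that
reduces its distance to a reference streamline; the mean polyline is then
re-resampled to s equidistant nodes. The reference is the streamline with
the largest endpoint separation (ties broken by lexicographic first point)
and is itself put into canonical orientation (lexicographically smaller
endpoint first), so the centroid is invariant to streamline storage order
and to how individual streamlines happen to be directed. One resolution
caveat: the final re-resampling walks the mean *polyline*, so a vertex
that falls between nodes is corner-cut at sub-node-spacing scale; for
dense, smooth streamlines this is far below voxel size.

Projection: every streamline vertex reads its metric value from the
containing voxel (nearest-voxel lookup by default, trilinear optional) and
is assigned to the nearest centroid node via a cKDTree. The node value is
the weighted mean with kernel `w = 1/(1 + d/h)`, where d is the vertex-to-
node distance and h the centroid's inter-node spacing — monotonically
decreasing and scale-normalized, so spurious streamlines far from the
bundle core contribute little (a Gaussian kernel is a config option).
"Distance" here is the Euclidean vertex-to-node distance normalized by
node spacing; this is an interpretation — an along-geodesic definition
would require a surface model that streamline data do not provide. Nodes
that receive no vertices are NaN and are excluded downstream (they also
break statistical clusters). Out-of-bounds vertices are dropped with a
logged count; profiles keep all 100 nodes (end-node trimming is off by
default).

## Along-tract statistics

Input is a subjects × nodes × metrics array per bundle (the cohort default
is 56 × 100 × 5 with metrics FW, FA, MD, AD, RD).

1. **Pruning.** Pairwise correlations are computed over pooled
   subject × node observations. While any |r| exceeds 0.8, the member of
   the worst pair with the larger mean |r| against all other metrics is
   removed (ties: the later metric in the canonical order). Greedy removal
   with this redundancy rule is deterministic and keeps the less-redundant
   member of each conflicted pair.
2. **PCA.** Retained metrics are z-scored over the pooled observations of
   both groups and reduced with a full-rank PCA; L is the smallest count
   reaching 80% cumulative explained variance. Components are sign-fixed
   so each one's largest-|loading| entry is positive — PCs are otherwise
   sign-ambiguous and effect directions would be irreproducible.
3. **Covariates.** Age, sex and center (intercept + dummy coding) are
   regressed out of every node × component series by OLS; residuals are
   orthogonal to the design to 1e-10. The regression is computed once on
   the observed data; permutations shuffle labels afterwards (a light
   Freedman-Lane scheme — the covariate fit is not redone per
   permutation).
4. **Tests.** Group comparison: two-sample Hotelling T² per node,
   `T² = n₁n₂/(n₁+n₂) · d̄ᵀ S⁻¹ d̄` with pooled covariance S, referred to
   the exact F distribution with (L, n₁+n₂−L−1) degrees of freedom; it
   reduces to the squared pooled t when L = 1. Score association (within
   the patient group): per node, a joint F-test of the L component
   coefficients in `AES ~ components + covariates`; the effect size r is
   the signed square root of the partial R² (sign of the dominant
   component coefficient; exactly the signed partial correlation when
   L = 1).
5. **FWE.** Labels (or scores) are permuted (default 10,000 times,
   calibration simulations use 500), per-node p-values recomputed, and the
   maximum run of contiguous p < α nodes recorded. The cluster-size
   threshold is the empirical (1−α) quantile (type "higher", rounded up,
   floor 1) of that null distribution; observed clusters at least that
   long are significant. Clusters are 1-D runs along the node index with
   no smoothing; NaN nodes break runs so significance cannot bridge
   unmeasured stretches. A permutation p for the observed maximum cluster
   is also reported with the standard (1 + exceedances)/(1 + n_perm)
   estimator.

Exchangeability note: permuting after a single covariate residualization
is slightly liberal in small samples relative to full Freedman-Lane; the
measured family-wise false-positive rate of the whole chain on 200 null
cohorts was within the nominal 5% plus Monte-Carlo slack.

## Synthetic data: what it emulates, what it does not

`gen_scheme` reproduces the *structure* of a cube-and-sphere (CUSP)
acquisition — 60 directions, an inner shell at b = 1000 plus cube
vertices/edges/faces whose effective b grows with the squared norm up to
3000 s/mm², one b0 — not any vendor's exact gradient geometry.
`simulate_voxel`/`gen_phantom` draw Rician magnitudes (two Gaussian
channels, σ = b0/SNR) around the mixture forward model. `gen_bundle`
builds line/arc/helix bundles with smooth per-streamline offsets and
pointwise jitter.

`gen_profiles` builds cohort profile datasets from two node-smooth latent
factors (moving-average width 5 nodes, restandardized) with fixed metric
loadings, plus independent per-metric noise, mapped to realistic metric
scales. The default loadings give a pooled FA-RD correlation of about
−0.84 — strong enough that the pruning stage always fires and always
removes RD (the more redundant member) — and make factor 1 dominate the
retained metrics' shared variance so the first principal component aligns
with it; loading columns are oriented by the same dominant-loading-positive
convention as the PCA, so a planted signed effect on a factor appears with
that sign on the matching component. Cohort defaults mirror a late-life
depression case-control design: 21 controls vs 35 patients, age ~ N(75, 6),
75% female,
two centers, apathy score ~ N(41.78, 8.71) in patients. Effects are
standardized mean shifts (group) or score slopes (association) added to a
latent factor over a stated node interval.

What passing tests therefore show: the estimators recover planted
structure under correctly specified noise, the selection and FWE
procedures are calibrated under the generator's correlation structure, and
the pipeline is deterministic. What they do not show: robustness to
misregistration, partial-volume mixtures at tract borders, non-Rician
(parallel-imaging) noise, segmentation errors, or real anatomical
variability — none of which the generator models.

## Problem sizes and defaults

Simulation-based checks use deliberately modest sizes chosen to exercise
the full chain: 50 seeded voxels for recovery and selection accuracy, 200
null cohorts × 500 permutations for FWE calibration, 50 cohorts for power,
and a small (4×2×2 voxel) phantom in the end-to-end demo. Production
defaults are higher (10,000 permutations; up to 3 compartments with 5
starts per candidate).

## Known limitations

- The per-voxel fit is local optimization with restarts; pathological
  crossing geometries can still find equivalent-likelihood swaps of
  compartments. Axis identity is only meaningful up to sign.
- AICc treats the softmax logits and angles as free parameters near the
  interior; for boundary fits (a weight driven to ~0) the effective
  dimension is lower, which slightly favors larger models — in practice
  offset by the small-sample correction.
- The score-association r for L > 1 compresses a joint effect into one
  signed number; per-component coefficients should be consulted when
  components carry opposing effects.
- Cluster-size FWE with the "≥ threshold" rule and a discrete null can be
  marginally liberal; the measured null family-wise rate stayed within the
  allowed band, and a stricter rule is one line away for conservative use.
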