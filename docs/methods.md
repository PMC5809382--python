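# Methods

This note documents the models, conventions and numerical choices
behind `musselshape`, and what the synthetic validation does and does
not establish.

## Elliptic Fourier analysis

A closed outline with vertices `(x_i, y_i)` is treated as a
piecewise-linear curve and decomposed into harmonics via exact
integrals over the polygon segments (the derivative is constant per
segment, so each Fourier integral is a sum of cosine/sine differences
at the segment breaks).

**Parameterization.** Two conventions are offered:

* `uniform` (default): each vertex advances the curve parameter by an
  equal step.  The known spectral attenuation of linear interpolation
  (`sinc²(πn/K)` for harmonic *n* of a *K*-gon) is divided out, which
  makes the transform *exact* for outlines sampled from a band-limited
  curve — a unit circle returns `(1,0,0,1)` and a pure ellipse a single
  harmonic, to machine precision, and forward∘inverse round trips are
  exact.  This is the right convention for outlines that are evenly
  sampled, including everything the synthetic generator emits.
* `chord`: the classic chain-length parameterization, where the
  parameter advances by each segment's chord length.  It is robust for
  unevenly digitised outlines but carries an O(K⁻²) interpolation bias,
  and an ellipse traversed at constant speed genuinely contains
  higher-harmonic content (a property of the parameterization, not an
  error).

The two coincide once an outline has been resampled to equal arc
length.  Note the subtlety that resampling *re-parameterizes* the
curve: coefficients measured after equal-arc-length resampling are the
arc-length-parameterized coefficients, which differ systematically from
uniform-parameter ones for the same shape.  For this reason the
pipeline leaves generated (already evenly sampled) outlines unresampled
by default (`RunConfig.resample_points=None`), while digitized file
input should be resampled (512 points is ample for 7 harmonics).

**Normalization.** Size is removed by the first-harmonic ellipse's
major semi-axis; rotation by aligning that axis with +x; the start
point is moved to the major-axis vertex.  The residual 180° start
ambiguity (which flips the sign of even harmonics) is resolved by
requiring the largest-magnitude harmonic-2 element to be positive —
stable provided that element is well away from zero, which the template
shapes guarantee by construction (the ventral template carries explicit
harmonic-2 asymmetry for exactly this reason).  When the first ellipse
is nearly circular (axis ratio > 0.95) its phase is numerically
meaningless, so orientation and start are anchored on harmonic 2 and
the remaining quarter-turn ambiguity is resolved by a deterministic
lexicographic rule.  Reflection is *not* removed: views are assumed
consistently sided, and removing it would destroy genuine asymmetry
signal.

**Harmonic calibration.** The cumulative power fraction
(`power_n = (a²+b²+c²+d²)/2`) is measured against a 24-harmonic
reference decomposition, so "n harmonics reach 98% of total power" is a
statement about the outline's full harmonic content, and an
unreachable threshold is a detectable error rather than a vacuous
success.

## Morphospace

PCA is the SVD of the column-centred coefficient matrix — covariance
scale, deliberately not correlation: coefficient variances carry
meaningful relative scale, and the score standardization needed for the
stacked model happens later, on the retained PCs only.  Loading signs
follow the "largest element positive" convention so reconstructions are
reproducible across runs.  `reconstruct_at` maps `mean ± k·SD` along a
PC back through the inverse transform; reconstruction of shapes far
outside the data cloud can self-intersect, which warns but still
returns the outline.

MANOVA uses `λ = det(E)/det(E+H)` with Rao's F approximation.  Site and
length are tested separately by default (the joint model is available
by calling the operation twice on residualised scores if wanted); the
statistic is invariant to orthogonal rotations of the score block.

## Species discrimination

Two-class LDA with pooled within-group covariance and priors
proportional to group sizes.  Standardized discriminant coefficients
(raw × pooled within-group SD) rank PCs by their contribution to
separation; the "species PCs" are the smallest leading set reaching 70%
of the total absolute contribution, extended to at least four.
Leave-one-out CV refits the model without each specimen.  Multi-class
discrimination is out of scope.

## The stacked additive mixed model

The response is the long table of standardized PC scores (one row per
specimen × PC).  Per PC stratum the mean structure has an intercept, a
centred linear length slope, and a cubic-regression-spline smooth of
each environmental covariate.  Smooths use the cardinal natural-spline
basis ("cr") with a fixed, small dimension — default 3 knots at the
covariate's min/median/max, hence 2 df per smooth after removing the
constant — i.e. unpenalized regression splines with manually chosen
flexibility.  With only ~15 distinct covariate values (site-level
predictors) more flexibility is not identifiable anyway.  Basis columns
are offset so they vanish at the covariate's sample mean, making the PC
intercept the prediction at "all covariates at their means".

**Estimation.** The site random intercept (shared across PC strata, as
the model equation specifies) and the residual variance function
`sd = σ·exp(δ_j·(v − v̄))` enter a profiled (RE)ML objective: for given
variance parameters `(ψ = σ²_Site/σ², δ₁…δ₅)` the fixed effects and σ²
have closed forms via a Woodbury identity (the grouping design makes
`Z'W⁻¹Z` diagonal), so each likelihood evaluation is O(n·p²).  The
remaining ≤ 6 parameters are optimised by L-BFGS-B with a Powell
polish; degenerate evaluations return a large finite penalty (1e10) so
numerical differentiation stays defined.  The variance covariate is
centred internally (σ then refers to the covariate mean; δ is
unaffected).  Bounds: `log ψ ∈ [−16, 12]`, `δ ∈ [−1.5, 1.5]`.

**Inference.** Per-term Wald F statistics use the model-based
coefficient covariance; the numerator df is the block size (edf).  The
denominator df follows a containment-style rule: observation-level
terms (length) use `n − p`; site-level covariate blocks use
`n_pc·q − q − n_pc·(1 + s)` where `q` is the number of sites and `s`
the number of site-level basis columns per stratum — site-level
information lives in the site × PC cell means net of the random
intercepts and cell parameters.  A null simulation at the study design
(15 sites, 5 PCs, n = 400 rows) puts the empirical type-I error at
α = 0.01 within Monte-Carlo error of nominal for both term types.
Significance is reported at α = 0.01 throughout.

**Selection and effect sizes.** AICc (`AIC + 2p(p+1)/(n−p−1)`) and
LRTs on declared nested pairs; variance structures are compared on REML
fits (identity vs `exp(temperature)` vs `exp(chla)`, each adding 5 δ
parameters), fixed-structure comparisons should use ML fits.  Effect
sizes default to the *linear-refit* definition: every smooth is
replaced by a linear term in the standardized covariate and the model
refitted; the effect is that slope (response SD per covariate SD) with
a normal 95% CI, significant when the CI excludes zero.  The
alternative reading — average first derivative of the fitted smooth
times the covariate SD — is available via `method="derivative"`; the
two agree for effects that are in truth linear, and neither is claimed
to be canonical.

## The synthetic generator

`generate_environment` draws site covariates uniformly within field
ranges (temperature 0–18 °C, salinity 6–35 psu, chl-a 0.5–5 mg m⁻³),
splits sites into large/medium/small systems (10:4:1), and can induce a
temperature–salinity correlation through a Gaussian copula to exercise
the collinearity branch.  `generate_dataset` builds each specimen's
coefficient vector as

    template + Σ_k g_k(covariate)·d_k + u_site·d_site + ε

over the 50 free coefficients (harmonic-1 `a,b,c` are pinned by
normalization), with mutually orthonormal factor directions, a logistic
salinity response (saturating at high salinity), linear length,
temperature and chl-a responses, `u_site ~ N(0, σ²_Site)` and isotropic
residual noise with `sd = σ·exp(δ·T)`.  Default magnitudes set the
variance hierarchy age > salinity > temperature > food > species
(σ_Site = 0.008, σ = 0.004, δ = −0.1 in coefficient units); they are a
design choice for testability with a realistic ordering, not measured
biology.  The species offset (0.016) acts only on harmonics ≥ 5, so
reference species overlap in PC1–PC2 but separate along later PCs;
reference populations use a randomized-block design (species alternated
down the within-site length ordering) so the offset is the only
systematic group difference.

`simulate_long_table` simulates the stacked response *directly on the
score scale*, exactly matching the mixed-model equation.  This is the
instrument for statistical validation (coverage, type-I error, LRT
power, boundary behaviour), because one geometric fact limits the
outline-level path: a single coefficient-space site displacement
direction cannot produce a site intercept that is *equal across the
five emergent PC strata* — after PCA rotation the site effect
concentrates in one PC, so σ²_Site and δ recovered through the full
outline pipeline are structurally attenuated rather than biased by any
implementation defect.  Relatedly, with only 15 sites, AICc selection
among variance covariates can latch onto chance correlations between a
covariate and realised site-level residual heterogeneity; the selected
structure should be read as descriptive, which is inherent to
variance-structure selection at small site counts.

What passing tests show about real data, and what they do not: the
geometry (EFA, normalization invariances, PCA reconstruction, TPS) is
validated analytically and holds for any input; the statistical
machinery is validated on data that satisfy the model's assumptions
exactly.  Real outlines add digitization noise, uneven sampling
(resample first), possible left/right inconsistency, and mean–variance
structure beyond the exponential family modelled here.

## Problem sizes

Test and acceptance runs use: 400-row stacked tables (80 specimens × 5
PCs) with 200 replicates for CI coverage, 300 for type-I calibration,
100 for LRT power; 300-specimen surveys (15 sites × 20) for the
pipeline quantities; 120 specimens for reference-species LOOCV.  These
sizes make Monte-Carlo error small relative to the tolerances while
keeping the default suite fast.

## Known limitations

* Smoothing-parameter selection is manual (fixed basis dimension);
  no penalized/automatic smoothness estimation.
* One grouping level (site); no spatial or temporal correlation
  structures.
* Two-class LDA only.
* The TPS correspondence between outlines is by arc-length index after
  equal resampling (pseudo-landmarks), adequate for near-aligned mean
  shapes but not a substitute for true landmarks.
* Wald/containment df and the χ² reference for variance-structure LRTs
  are approximations; both were checked by simulation at the default
  design only.
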