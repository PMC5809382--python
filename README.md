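# musselshape

Quantitative analysis of blue mussel (*Mytilus* spp.) shell-shape
plasticity along environmental gradients: elliptic Fourier outline
analysis, PCA morphospace, species discrimination, thin-plate-spline
deformation grids, and a stacked additive mixed model linking shape to
temperature, salinity and food availability.

The package is aimed at geometric-morphometrics and marine-ecology
workflows in which closed 2-D outlines of shells (a lateral and a
ventral view per specimen) are the raw data, and the questions are:
How does shape vary across sites and with age?  Which shape features
separate species?  How much of the shape variance do environmental
gradients explain, and does shape *heterogeneity* itself change along
those gradients?  A first-class synthetic-data generator reproduces the
statistical structure of such a survey (15 sites in three study
systems, shell lengths 25–81 mm, site random effects, residual spread
varying with temperature), so every stage can be exercised and
validated without any specimen imagery.

## The model

**Outline descriptors.** A closed outline decomposes into elliptic
Fourier harmonics, four coefficients each:

    x(t) = A0 + Σₙ aₙ cos(nt) + bₙ sin(nt)
    y(t) = C0 + Σₙ cₙ cos(nt) + dₙ sin(nt)

computed by exact integrals over the polygon segments.  Normalization
removes translation, size (first-ellipse major semi-axis), rotation and
starting point, leaving pure shape.  Seven harmonics per view, both
views concatenated, give a 56-coefficient shape vector per specimen.

**Morphospace.** PCA (covariance, SVD) of the shape vectors yields
shape variables PC1, PC2, …; any morphospace point reconstructs to an
outline pair, so PC extremes (mean ± 3 SD) are directly visualisable,
and thin-plate splines between reconstructions give deformation grids
and iso-deformation fields.  Wilks'-λ MANOVA tests site and shell-length
effects; two-class LDA with leave-one-out cross-validation and
standardized discriminant coefficients isolates species-linked PCs.

**Environmental model.** The first five PC scores are standardized and
stacked into one response `ShapeVar_ijk` (site *i*, PC *j*, specimen
*k*), modelled as

    ShapeVar_ijk = f(Temp_i)·PC_j + f(Sal_i)·PC_j + f(Chla_i)·PC_j
                   + Length_ik·PC_j + PC_j + Site_i + ε_ijk
    Site_i ~ N(0, σ²_Site),      sd(ε_ijk) = σ·exp(δ_j·v_i)

with cubic-regression-spline smooths `f`, a site random intercept, and
an optional exponential variance function in a covariate *v*
(temperature or chl-a) with one δ per PC stratum.  Estimation is
profiled (RE)ML; models are compared by AICc and likelihood-ratio
tests, and per-covariate effect sizes (per 1 SD) come with 95% CIs.

## Worked example

`examples/` holds one short script per capability.  The core loop —
generate a survey, measure shape, model it — looks like:

```python
from musselshape import gamm, morphospace, outline_io, synth
from musselshape.efa import assemble_shape_matrix, efa_forward, efa_normalize

env = synth.generate_environment(15, seed=1)
ds = synth.generate_dataset(env, 20, synth.GeneratorConfig(seed=2))
coeffs = {
    sid: {v: efa_normalize(efa_forward(outline_io.orient_outline(o), 7))
          for v, o in views.items()}
    for sid, views in ds.outlines.items()
}
model = morphospace.fit_pca(assemble_shape_matrix(coeffs))
table = gamm.stack_scores(model.scores, model.specimen_ids,
                          ds.specimens[["specimen_id", "site_id", "length"]],
                          env[["site_id", "temperature", "salinity", "chla"]])
fit, comparison = gamm.select_variance_structure(table)
```

Running `python examples/03_morphospace.py` prints:

```
% variance of the first five shape PCs:
  PC1:  52.9%
  PC2:  21.8%
  PC3:   8.2%
  PC4:   4.8%
  PC5:   2.2%
PC1 -3SD lateral area 1.868 vs +3SD 1.923 (normalized units)
MANOVA site: Wilks lambda=0.0000, approx F=70.27, p=0
MANOVA length: Wilks lambda=0.0036, approx F=8081.08, p=0
```

PC1 dominates because shell length (age) drives the largest share of
shape variance in the generated survey; the tiny Wilks' λ values say
that both collection site and shell length displace specimens strongly
in the 10-PC morphospace.  `examples/04_species_lda.py` then classifies
the two synthetic reference species from shape alone (100% leave-one-out
accuracy at the default species offset), and
`examples/06_gamm_environment.py` fits the stacked model, selects the
residual variance structure and prints per-PC effect sizes.

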