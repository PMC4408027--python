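# Methods

This note documents the models and numerical choices behind `twigwood`:
what the estimators assume, what the synthetic generators do and do not
emulate, and where design decisions were genuinely open.

## Point-count stereology

Tissue area fractions are estimated by the classical point-count design: a
square lattice of points is overlaid on a labeled cross-section and each
point is tallied to the tissue of the pixel it lands on. The estimate for
tissue *t* is `p̂_t = n_t / n`, with the binomial standard error
`√(p̂(1−p̂)/n)` attached. Design choices:

- **Points are pixel centres and take the pixel's label.** Labels are
  exhaustive and mutually exclusive, so there is no boundary ambiguity to
  adjudicate; a human annotator classifying printed points faces one, but a
  label map does not.
- **Denominator.** Points outside the analysed sector, or on pith, are
  excluded; all fractions are of the wood cross-section proper. Estimated
  fractions therefore always sum to 1.
- **Sampling design.** Defaults follow the conventional protocol: 300 px
  spacing (84.3 μm at the 0.281 μm/px reference digitization) and a minimum
  of 300 analysed points per sample, enforced as a warning by default and
  an error in strict mode.
- **Unbiasedness.** With a uniformly random grid offset the estimator is
  design-unbiased for any structure size; the binomial variance model is
  additionally accurate when the spacing exceeds the largest single
  structure, so that neighbouring points fall in different cells. On the
  synthetic mosaic one more condition matters: the mosaic is periodic
  (fibre cells of fixed diameter, regularly spaced bands), and a grid
  whose spacing is commensurate with those periods aliases against them,
  inflating the variance well beyond binomial. The sampling-theory checks
  therefore use a *prime* spacing (101 px on a 2000 px section, about 400
  points). Real micrographs are aperiodic and do not need this care, but
  the 300 px default is kept for fidelity to the standard protocol.

## Vessel morphometrics

Vessel lumens are 4-connected components of the vessel-lumen label;
components whose centroid falls outside the sector are dropped. Areas are
converted to mm² by the pixel scale. Two conventions required a decision:

- **"Diameter" is the circle-equivalent diameter** `d = 2√(a/π)` computed
  from the lumen area. For the synthetic disc geometry this is exact; for
  real, slightly elliptical lumens it is the standard convention.
- **The small-conduit rule uses the maximum Feret diameter** with a strict
  inequality (below 15 μm), so a conduit at exactly 15 μm counts as a
  vessel.

The derived statistics are algebraic identities: `A` is the arithmetic
mean lumen area, `N = VLF/A`, `S = A/N = A²/VLF`, and `D_H = Σd⁵/Σd⁴`.
`N·A = VLF` and `S·N = A` hold to machine precision by construction, and
`D_H` is never below the mean diameter (power-mean ordering, checked
property-based). The vessel lumen fraction supplied to `N` defaults to the
grid estimate for the same section — mirroring the measurement protocol —
but a component-area VLF can be passed instead.

## Derived traits

- **Wood density**: oven-dry mass over water-saturated volume, the volume
  read off as the mass of displaced water at 1.0 g cm⁻³.
- **MOE**: the three-point-bending protocol fixes only the test and the
  span rule (span ≥ 20× diameter, to keep shear negligible); the formula
  is standard beam theory, `MOE = m L³ / (48 I)`, with the elliptical
  second moment `I = π a b³ / 64` taken over the whole specimen including
  bark and pith, because that is what is physically bent.
- **SLA** is leaf area per dry mass (cm² g⁻¹), so that `LMA = 1/SLA`;
  **LA/SA** adds the SLA-subset leaf area to SLA × remaining leaf mass and
  divides by the elliptical sapwood area (bark and pith excluded).
- **Approximate cell-wall material density** is the ratio of wood density
  to the fibre+vessel wall fraction. It is explicitly an approximation: it
  ignores parenchyma and small-conduit walls, so it overstates the true
  wall density less than a naive solid-fraction ratio would, and values
  near 1.5 g cm⁻³ are the plausibility anchor.
- **Aggregation** is the arithmetic mean per species-at-site; a species
  sampled at two sites is two entities. N-fold variation is max over min
  *positive* value — zeros mean the tissue is absent, and the overview's
  low/average/n-fold for such traits use only the species where the tissue
  occurs.

## Normality-gated correlations

Species means are screened with Shapiro–Wilk; a trait is "approximately
normal" when p > 0.05. A pair of traits is correlated with Pearson's r
when both are normal, Spearman's ρ otherwise; p values are two-sided and
banded at 0.05/0.01/0.001. Missing values are deleted pairwise and n is
reported per pair. Base-10 log transforms are available per trait for the
screen (the conventional stabilizer for right-skewed traits such as vessel
number per area or stiffness). No multiple-testing correction is applied —
with ~200 simultaneous pairs the individual tests are descriptive — and the
suite asserts the reported p values are the raw test p values. The gate's
type-I error on independent normal traits is nominal (5% ± 2 points over
1000 replicates, checked in the acceptance suite).

## Synthetic sections

The mosaic generator is built so that every requested composition is
realized with a pixel-exact oracle:

1. **Discs first** (mucilage canals, then vessels, then small conduits),
   placed by dart throwing with no overlap and fully inside the frame.
   Vessel lumen diameters are lognormal truncated to ≥ 15 μm (median 45 μm,
   σ_log 0.30 by default); conduit diameters are truncated below 15 μm.
   Each vessel carries a concentric wall annulus whose thickness
   `t = r(√(1+ρ)−1)` realizes the requested wall:lumen area ratio ρ.
   A greedy stopping rule adds a disc only while it brings the realized
   area closer to the target, so the residual is at most half a disc.
   Packing failure raises an infeasibility error naming the tissue.
2. **Bands next**: rays as vertical and axial parenchyma as horizontal
   bands, painted column-by-column against the exact count of still
   unassigned pixels (residual ≈ one band column). Bands meander
   sinusoidally — as rays bend around vessels — which also prevents any
   straight grid line from lying entirely inside or outside a band.
3. **Fibres fill the remainder** as a hexagonal tessellation (20 μm cells
   by default, random lattice phase). The wall/lumen split thresholds the
   distance to the nearest cell boundary at the exact sample quantile of
   the requested wall share, so the split is pixel-exact up to ties.

Realized fractions land within ±0.003 of targets in practice, well inside
the ±0.02 contract, which itself is far below grid-sampling noise at 300
points. The generator is deterministic given its seed, and its metadata
records the true vessel and conduit diameters for the morphometrics stage.

**What the mosaic does not emulate:** growth rings, tension wood, vessel
multiples and groupings, radial sector geometry (sections are rectangular
with a full mask), image noise or segmentation error. Passing tests show
the estimators are correct on exhaustively labeled input; they say nothing
about upstream segmentation quality on real micrographs.

## Synthetic trait cohorts

The cohort generator emulates a species-level survey of twig wood in a
narrow density band (0.38–0.62 g cm⁻³) across three climatically
contrasting sites. Fixed design: 69 species-at-sites split 41 rainforest /
11 woodland / 17 temperate; small conduits present in 2, 10 and 14 species
per site respectively (26 total, assigned to the highest latent conduit
propensity within each site); mucilage canals in 3 rainforest species.
Other cohort sizes scale these counts proportionally.

Values are drawn by a Gaussian copula over latent drivers: the composite
totals (total parenchyma TPF, total fibre TFF), the minor fractions (VLF,
VWF, conduit fraction), vessel area, and the ecological traits (pith area,
density, heights, MOE, LA/SA), plus two split shares (fibre-wall share of
total fibre; axial share of total parenchyma). The latent correlation
defaults to the published species-level coefficients among those traits,
projected to the nearest valid correlation matrix (one Higham eigenvalue
clip); the shares carry a few structural correlations (wallier fibres in
denser, stiffer wood; larger axial share with larger vessels).

- **Marginals** are scaled Beta distributions on the published (low, high)
  ranges with the published mean. The concentration (α+β = 4) is set so
  that a cohort-sized sample spans most of the stated range (range ≈ 4.5
  sd for n ≈ 69); replicate noise is multiplicative with a default CV of
  0.1 (the within-species variance is not published; this default is a
  stated guess).
- **Closure.** The eight base fractions must sum to 1. The minor fractions
  keep their marginals and the fibre+parenchyma block absorbs the
  remainder: TPF and TFF are rescaled by `(1−R)/(TPF+TFF)` where R is the
  minor-fraction sum. The strong negative fibre–parenchyma correlation is
  therefore partly closure geometry — exactly as in real compositional
  data — modulated by the latent entry.
- **Calibration.** Because closure distorts the correlation of the closed
  composites, the internal latent TPF–TFF entry is calibrated by bisection
  against a 4000-species rehearsal draw (fixed internal seed, common
  random numbers, the full composition path including presence masking) so
  that the composites realize the requested value. With the default
  −0.86, the realized mean over 200 cohorts of 69 species is −0.865
  (±0.028 sd per cohort). The calibration is deterministic and cached.
- **Derived columns.** N and S come from their identities (`VLF/A`,
  `A²/VLF`); D_H is 1.18 × the equivalent diameter of the mean vessel
  area with mild lognormal jitter (σ_log 0.08), reproducing the observed
  D_H range without making it a deterministic function of A. Replicates
  re-close the fractions and re-derive composites and vessel statistics so
  every record satisfies the identities exactly; the literature-sourced
  maximum height is constant across replicates.

**What the cohort does not emulate:** phylogenetic structure, real
site-climate effect sizes beyond the presence patterns, trait-specific
measurement error models, or the exact shapes of the empirical marginals
(only range and mean are matched). Tests that recover the latent
correlation show the generator honours its own contract, not that the real
data were generated this way.

## Numerical details and degenerate inputs

- Correlation matrices are symmetric with unit diagonal by construction;
  the headline entry always equals the Pearson or the Spearman entry as
  gated by the two traits' normality flags. Spearman uses average ranks
  for ties.
- Constant traits are skipped by the normality screen and dropped from
  correlation matrices, each with a warning; Shapiro–Wilk on fewer than 3
  values or a constant vector is an error when called directly.
- All-zero traits summarize to a zero row with undefined n-fold; n-fold on
  an all-zero vector is an error.
- The copula factorizes the latent matrix by eigendecomposition (not
  Cholesky) so positive *semi*definite matrices are accepted; an
  indefinite matrix raises an error carrying the nearest valid correlation
  matrix as a suggestion.
- Label maps round-trip through indexed PNG with a JSON sidecar; a full
  256-entry palette is written so indices are preserved verbatim, and
  unknown indices on read are reported by value.

## Problem sizes

The test suite and the acceptance script use a 2000×2000 px section at
1 μm/px (≈ 400 grid points at 101 px spacing, 200 random offsets) for the
sampling-theory checks, 200 cohorts of 69 species for correlation
recovery, and 1000 null replicates for the gate's type-I error; the whole
suite runs in well under a minute on one core. These sizes were chosen so
the Monte-Carlo standard errors are several times smaller than the bands
being checked.
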