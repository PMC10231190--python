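# Methods

## The square-root temperature model

Community-level rates of bacterial growth (leucine incorporation), fungal
growth (acetate-in-ergosterol incorporation) and basal respiration are
modelled on the square-root scale as

    sqrt(R) = a (T − Tmin) (1 − exp(b (T − Tmax)))

with cardinal temperatures Tmin (lower x-intercept), Tmax (upper
x-intercept) and a rate maximum at Topt strictly between them.  Below the
optimum the exponential term is close to 1 and the model reduces to the
linear sub-optimal form sqrt(R) = a (T − Tmin).  The model is descriptive,
not mechanistic: Tmin and Tmax are apparent community-level intercepts, and
a community's thermal trait distribution is summarised by where these
cardinal temperatures sit.

Assumptions worth keeping in mind: measurement error is treated as additive
Gaussian on the sqrt-rate scale (the scale on which all fitting happens);
rates are non-negative, and observations at temperatures outside the niche
floor at zero; each site × process curve is fitted independently (no
pooling or hierarchical structure).

## Fitting procedure

1. **Sub-optimal stage.**  OLS of sqrt-rate on temperature over the
   sub-optimal window — 0–25 °C for growth processes, all assay points
   (0–45 °C) for respiration, which does not reach an optimum in this
   interval.  Tmin = −intercept/slope.  Gross outliers are excluded
   iteratively: the point with the largest externally (deletion) studentized
   residual is dropped when |t| > 3, at most 2 points, never below 4
   remaining.  (The internal variant is bounded by sqrt(n−2) ≈ 2 at a
   6-point window and could never reach 3.)  A user-supplied exclusion mask
   is honoured before fitting.  Fits with non-positive slope are flagged
   invalid.
2. **Full stage.**  With (a, Tmin) fixed, bounded least squares on the sqrt
   scale estimates (b, Tmax) over all points, with b ∈ (0, 5] per °C and
   Tmax ∈ (warmest rising temperature, 80] °C; initialisation b = 0.1,
   Tmax = warmest assay temperature + 5 °C; three seeded random restarts on
   non-convergence.  The modelled sqrt-rate is clipped at zero inside the
   residual so that zero observations beyond the niche are representable.
3. **Joint polish (default, `refine_all=True`).**  All four parameters are
   refined together from the staged estimates.  This matters when b is
   small: the exponential term then suppresses the sub-optimal window by up
   to tens of percent (factor 1 − exp(b(25 − Tmax))), and strictly fixed
   stage-1 estimates of (a, Tmin) would be biased.  On noise-free
   model-generated curves the polished fit recovers all four parameters to
   better than 1e-6 relative.  `refine_all=False` reproduces the literal
   two-stage procedure.

Curves that keep rising through the warmest assay point push Tmax into its
upper bound, or place Topt beyond the data; both are flagged `no_optimum_`
and the fit is marked non-converged, so downstream analyses use only the
sub-optimal parameters (this is the expected behaviour for respiration).
Topt is the unique root of the derivative of the modelled curve in
(Tmin, Tmax), found by Brent bracketing to 1e-9 °C (the slope a drops out).
Normalisation divides observed rates by the *modelled* rate at Topt — the
model defines the maximum off-grid — and is undefined for fits without an
optimum.

Q10 over an interval [T_lo, T_hi] with T_hi − T_lo = 10 °C is the closed
form ((T_hi − Tmin)/(T_lo − Tmin))²; the default interval is 5–15 °C.  The
slope a cancels, so Q10 is a pure, convex, increasing function of Tmin.

## Trait-level statistics

All analyses are complete-case: a site whose fit failed simply drops out of
that analysis and the residual degrees of freedom shrink accordingly.
Simple trait–climate regressions report slope, intercept, R², F = t²(slope)
and p on (1, n−2) degrees of freedom.  The seasonal ANCOVA uses sequential
(type-I) sums of squares with the climate covariate entered first, then
sampling season, then their interaction — climate is the designated
predictor, season the nuisance covariate.  The paired seasonal comparison is
a classical paired t test on winter − summer differences (a zero-variance
difference vector with non-zero mean is reported as degenerate rather than
an infinite statistic).  The multiple regression of a trait on pH, SOM, MAT
and MAP reports per-predictor VIF_j = 1/(1 − R²_j) with a warning above 10
and an error on exact collinearity.  Carbon availability is proxied as the
respiration rate at the assay point nearest 20 °C divided by SOM
(configurable reference temperature), and Pearson-correlated with MAT.
p-values are two-sided throughout and the trait-regression family is not
multiplicity-corrected, matching the survey-style reporting the pipeline
emulates.

## Community linkage

Alpha diversity is the Shannon index in nats and richness, computed on
unfiltered counts.  For beta diversity, ASVs with fewer than 5 total counts
are removed, samples are scaled deterministically to the minimum sample
depth (proportional scaling, not rarefaction: no subsampling randomness, no
zeros created, richness preserved), and Bray–Curtis dissimilarities are
ordinated by non-metric MDS (SMACOF with monotone regression, 20 seeded
random starts, normalised stress-1 reported).  External variables are
projected onto the ordination envfit-style: least squares of the variable on
the centred coordinates gives a unit direction and R², and significance
comes from permuting the variable (p = (1 + #{R²_perm ≥ R²})/(n_perm + 1),
999 permutations by default).  The ASV screen Pearson-correlates each ASV's
relative abundance with per-sample Tmin; warm-adapted taxa are significant
positive correlations, cold-adapted negative, at raw α = 0.05, with
Benjamini–Hochberg adjusted p-values reported alongside (Spearman available
via `method=`).

## The synthetic-survey generator

The generator emulates a 72-site continental survey: MAT uniform on
[−3.1, 18.3] °C; summer/winter monthly means at MAT ± a jittered 8 °C
half-amplitude; pH uniform on [4, 8]; SOM log-uniform on [2, 80] %; MAP
uniform on [400, 1800] mm yr⁻¹ and independent of MAT (keeps the multiple
regression identifiable; a correlation can be injected for VIF tests);
sampling season alternating.  True traits follow
Tmin = β0 + β1·MAT + N(0, σ²) per process with defaults

| process          | β0 (°C) | β1 (°C/°C) | σ (°C) | a range     | b range     | Tmax range |
|------------------|---------|-----------|--------|-------------|-------------|------------|
| bacterial growth | −11.0   | 0.20      | 2.2    | 0.02–0.06   | 0.08–0.18   | 43–51 °C   |
| fungal growth    | −8.0    | 0.07      | 1.8    | 0.015–0.05  | 0.08–0.30   | 40–52 °C   |
| respiration      | −5.8    | 0.10      | 1.1    | 0.02–0.06   | —           | —          |

β1 are the field-survey space-for-time coefficients; β0 and σ are
back-computed so that (i) the implied Tmin ranges match the field ranges
(about −14…−5 °C bacteria, −11…−4 °C fungi, −8…−2 °C respiration) and
(ii) the Tmin~MAT regression R² matches the value implied by the field F
statistics (R² = F/(F + df2): 0.24, 0.05 and 0.24 respectively) given
var(MAT) = 38.2 for a uniform MAT on the survey range.  a, b and Tmax are
drawn independently of MAT; draws with Tmax − Tmin < 30 °C are redrawn.
Respiration curves are generated from the sub-optimal line only (no optimum
within the assay range), growth curves from the full model.

Observed rates are max(sqrt-model(T) + ε, 0)² with ε ~ N(0, noise_sd²) at
the 0–45 °C ladder.  The default noise_sd = 0.02 sqrt-rate units (≈1 % of a
typical curve maximum) keeps the full-pipeline Tmin RMSE below 1 °C
(measured 0.84/0.82/0.44 °C for bacteria/fungi/respiration), so measurement
error stays small against the 1.1–2.2 °C between-site trait scatter that
carries the regression F statistics.

Synthetic communities are one sample per site: log-normal baseline
abundances over 400 ASVs, 50 planted "warm" ASVs whose log-abundance rises
with the site's true Tmin z-score (coupling 0.5), 50 "cold" ASVs falling
with it, 100 ASVs coupled to pH, multinomial counts at depth 10,000.  The
16S table couples to bacterial Tmin, the ITS table to fungal Tmin, and the
planted ASV identities are emitted as truth lists for power checks.

What the generator does *not* emulate: spatial autocorrelation among sites,
seasonal dynamics beyond a constant offset option, substrate depletion
during assays, compositional correlation between covariates (pH, SOM, MAT
are mutually independent by default), sequencing artefacts (chimeras,
primer bias), or non-Gaussian trait scatter.  Passing tests therefore
demonstrate estimator correctness and calibration under these idealised
conditions, not robustness to every property of field data.

## Replicate-survey slope recovery

`thermotrait.recovery.replicate_slopes` (driven by `scripts/acceptance.py`)
runs 500 independent surveys per process through the full pipeline and
averages the recovered Tmin-vs-MAT and Q10-vs-MAT slopes.  With the default
calibration the mean recovered Tmin slopes reproduce the generating (field)
coefficients to within Monte-Carlo error.  The recovered Q10 slopes run
somewhat above the values implied by evaluating the Q10 derivative at the
mean Tmin (≈0.037/0.018/0.042 vs 0.03/0.02/0.03 per °C MAT): Q10 is convex
in Tmin, so Gaussian trait scatter raises the expected slope
(E[f′(Tmin)] > f′(E[Tmin])).  This is a property of the Gaussian scatter
model, documented rather than tuned away; an empirical trait distribution
with a lighter warm tail yields slopes closer to the lower values.

## Numerical choices and limitations

- Optimiser: scipy `least_squares` (trust-region reflective) with analytic
  Jacobians, ftol/gtol 1e-10, xtol 1e-12; the suboptimal OLS is closed-form.
- Problem sizes were chosen so the whole validation suite runs on a single
  CPU in minutes: 500 replicate surveys for slope recovery, 200 replicates
  for permutation-calibration checks, 100 random draws for round-trip and
  Topt-oracle checks.
- Degenerate inputs: fewer than 4 usable points, non-positive sub-optimal
  slope, constant predictors/variables, zero-depth samples and all-zero
  sample pairs all raise informative errors rather than propagating NaNs.
- NMDS stress depends on random starts; runs are seeded and the best of 20
  starts is kept, but stress values are only comparable under equal seeds.
- The ASV screen tests each ASV marginally on relative abundance; it
  ignores compositional coupling between ASVs, so its raw-p discoveries are
  a screen, not inference on absolute abundances.
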