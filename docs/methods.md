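# Methods

This note records the models implemented in `forestdiv`, the conventions
chosen where several are defensible, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter for
reproducibility.

## Abundance currency

All community metrics weight species by **relative basal area**: a stem of
diameter `d` cm contributes π(d/200)² m², and a species' weight is its share
of the plot total. This one currency is used for FDis, RaoQ, Simpson/Hill
and the phylogenetic metrics alike, so that the facets of diversity are
directly comparable within a plot. (Simpson's index is classically defined
on individual counts; `simpson_index` accepts counts too, but the pipeline
scores basal-area shares for consistency with the trait weighting.)

## Functional dispersion

FDis is the abundance-weighted mean distance of species to the weighted
centroid of the community in trait space. Two paths exist:

- **Numeric-only traits**: each trait is z-scored with the sample standard
  deviation (n−1) and the space is Euclidean. The two-species example with
  trait values {0, 2} and equal weights gives exactly 1/√2.
- **Mixed traits**: Gower dissimilarity (numeric traits range-normalized,
  categorical traits 0/1 mismatch, pairwise-missing exclusion with
  renormalization, zero-range traits skipped with a warning) followed by a
  principal-coordinates embedding of the square-rooted dissimilarities.
  The square root renders Gower distances Euclidean in practice; axes with
  non-positive eigenvalues are dropped.

Standardization and Gower ranges are computed over the **whole trait table**
(the species pool), not per community. This is what makes FDis insensitive
to richness manipulations: duplicating a species into two equal-weight
identical-trait pseudo-species, or adding a zero-weight species, leaves
FDis unchanged to 1e−10 — both properties are tested. RaoQ uses the plain
(unsquared) Gower distances for consistency with the FDis distance space.

## Phylogenetic metrics

The tree is consumed as Newick (branch lengths required, quoted labels
supported) and must be ultrametric within 1e−6 relative tolerance (a
warning, not an error). Patristic distances, the Brownian-motion
variance–covariance matrix and per-edge tip sets are cached per tree.

- **MPD** (abundance-weighted): `Σ_{i≠j} aᵢaⱼdᵢⱼ / Σ_{i≠j} aᵢaⱼ`; self
  pairs are excluded and weights renormalized over the included pairs, the
  convention of the standard toolchain. With equal weights this equals the
  unweighted mean to 1e−12 (tested). Raw MPD is reported; ses(MPD) is
  provided alongside.
- **MNTD**: the (weighted) mean over species of the distance to the nearest
  other community member.
- **Faith's PD** is **root-inclusive**: a convention has to be fixed so a
  single-species community is defined; it scores the root-to-tip path.
- **Frequency null model**: each species' abundances are permuted across
  the plots where it occurs, so the occurrence (presence) pattern is
  preserved while abundance–plot associations are destroyed; the weighted
  MPD is recomputed each iteration (default 999, configurable) and
  `ses = (obs − null mean)/null sd`. Plots whose null distribution is
  constant up to floating-point jitter get a missing ses with a warning.
  Under self-null data the ses ensemble has mean ≈ 0 and sd ≈ 1 (tested
  over 200 matrices).
- **Blomberg's K** follows the MSE-ratio formulation: with the
  phylogenetically corrected mean â = (1ᵀV⁻¹x)/(1ᵀV⁻¹1),
  K = [(xᵀx-type MSE₀)/(V-weighted MSE)] / [(tr V − n/1ᵀV⁻¹1)/(n−1)].
  K ≈ 1 under Brownian motion (simulation-calibrated to [0.8, 1.2] on a
  100-tip tree), ≈ 0 for white noise. Significance: tip shuffling with
  `p = (1 + #{K_perm ≥ K_obs})/(1 + n_perm)`; the +1 correction avoids
  p = 0 at finite permutations.

## Climate derivations

- **CWD recursion** (default `cumulative` mode):
  `WDₘ = min(0, WDₘ₋₁ + Pₘ − PETₘ)`, reset to zero at the start of each
  hydrological year anchored at the climatologically wettest calendar month
  (ties broken earliest). The literal month-by-month reading
  `min(0, P − PET)` is exposed as `--cwd-mode monthly` because the verbal
  definition is ambiguous; the cumulative reading is the one consistent
  with "MCWD = min(CWD1…CWD12)".
- **MCWD over a window** is the mean of yearly CWD minima — a climatology
  characterizing typical conditions — not the single most negative year.
  Windows are the 30-year spans 1964–1993 and 1984–2013 and the full
  1964–2013 term; absolute changes are T2 − T1, so drying is negative.
- **SPEI**: 12-month trailing sums of P − PET, fitted per calendar month
  with a three-parameter log-logistic via probability-weighted moments
  (plotting position (i − 0.35)/n) and mapped through the fitted CDF to
  standard-normal quantiles. Samples the right-skewed family cannot
  represent (slightly left-skewed months arise easily in near-Gaussian
  synthetic data) are fitted mirrored and mapped through the complementary
  CDF; truly degenerate months (zero interannual variance) come back as
  missing with a warning, never as a crash. On stationary noisy series the
  index calibrates to mean ≈ 0, sd ≈ 1.

## Rates, grouping and the two-group model

Annual rates are `(X_T2 − X_T1)/(t₂ − t₁)` in decimal years; census
intervals under 10 years are flagged. Plots are **dry** iff their T1 MCWD
≤ −250 mm (inclusive), else wet.

The two-group comparison is the robust BEST-style model: observations in
each group follow Student-t(ν, μ_g, σ_g) with shared ν. Priors: μ ~ N(0, 10);
σ uniform on (sd_pooled/1000, sd_pooled·1000); ν ~ 1 + Exponential(mean 29)
(the "broad uniform" / "shifted exponential" defaults of the reference
implementation, whose exact hyperparameters the analysis description leaves
open). "Prob" is operationalized as the **probability of direction** of
μ_dry − μ_wet — the posterior mass on the dominant side of zero — which can
legitimately sit near 50% for weak differences.

## Driver regressions and model selection

Drivers with missing values are excluded; constant drivers are dropped; of
every remaining pair with |Pearson r| strictly above 0.7, the lower-priority
member is dropped (priority is a configuration choice — ecological
meaningfulness is a human judgement). Soil variables are centred, scaled
and eigen-decomposed; axes explaining ≥ 10% of variance are selected, and
each axis is oriented so its largest-|loading| variable loads positively
(reproducible signs across platforms).

The default candidate grammar emits exactly 35 models per response:
intercept-only; each single driver; climate-only pairs and triple;
soils-only pairs and triple; climate triple plus one PC; the full additive
model; the full model plus each single PC×climate interaction (9), plus
each PC's full climate block (3), plus each climate driver's full PC block
(3); and the full model with all nine interactions. Every spec includes
plot area as a covariate. The composition (beyond the count and the
best-model shapes) is configuration, since only those anchors are fixed.

Each model is Gaussian with predictors standardized internally; priors are
N(0, 2.5) on coefficients, N(0, 10) on the intercept (both on the
standardized scale) and Exponential(rate 1/sd(y)) on σ. Sampling is Gibbs:
the coefficient block is conjugate multivariate normal given σ, and log σ
takes a slice-sampling update. Selection uses **exact leave-one-out**: each
model is refitted n times (standardization recomputed within the fold), the
held-out point scored by the Monte-Carlo posterior-predictive density,
ELPD summed and LOOIC = −2·ELPD; the refit path agrees with a σ-grid
quadrature oracle to 0.05 per point (tested). ROPE defaults to the fraction
of the 89% HDI inside ±0.1·sd(y); adjusted R² is the classical formula at
posterior-median coefficients. Split-chain (rank-free) R̂ gates every fit:
values above 1.05 flag it unusable for selection, never silently.

## Samplers

No general-purpose MCMC framework is required: both models use Gibbs
schemes with stepping-out slice sampling (Neal 2003) for the non-conjugate
scalars (σ, ν), which is tuning-free and, unlike random-walk Metropolis,
comfortably meets R̂ < 1.01 at the default budget of 3 chains × 2000
iterations with the first half discarded as warmup. For the two-group model
all five parameters are slice-updated against the marginal Student-t
likelihood; an earlier latent scale-mixture Gibbs variant mixed poorly in ν
and was replaced. Numerical supports are bounded (log σ within
[−6, +8] of log sd(y) in the regression) so rank-deficient designs
(p ≈ n) cannot overflow the conjugate update; posterior mass at those
bounds is negligible in any identified fit.

## The synthetic-data generator

The generator produces the study *design*, not forest dynamics:

- **Phylogeny**: pure-birth (Yule, rate 1) tree rescaled to unit height —
  metrics depend only on relative branch lengths. The simulator's final
  speciation leaves zero-length pendant edges, so the clock runs one extra
  exponential waiting time before rescaling (this also keeps the trait
  variance–covariance matrix well-conditioned).
- **Traits**: Brownian motion along branches (numeric), iid normal
  ("white noise"), or categorical via thresholding a latent Brownian trait
  into equal-frequency classes (leaf habit with 2 classes, guild with 3,
  nitrogen-fixing with 2) — so categorical traits carry signal too.
- **Climate**: per plot, a seasonal precipitation sinusoid whose mean is
  bisection-calibrated so the stationary MCWD hits a point on the −320 to
  −150 mm baseline gradient (straddling the −250 mm split, comparable to
  the published −300 to −167 mm span); a linear fractional drying trend
  calibrated to per-plot MCWD changes from −27.5 mm (driest) to −7.5 mm
  (wettest); constant-climatology PET near 100 mm/month; VPD rising where
  precipitation falls; multiplicative lognormal noise (σ = 0.08).
- **Communities**: 21 plots, ≈80 species from a 140-species pool, ≈500
  stems ≥ 10 cm per hectare (plot-level totals are not published; these are
  plausible tropical-forest magnitudes), censused around 1989 and 2011.
  True annual rates follow `rate = α + β·ΔMCWD_Abs + ε` per facet with
  β > 0, so drier plots decline; magnitudes (≈10⁻⁴/yr for FDis and
  Simpson) mirror the published order of magnitude. The second census is
  engineered by rank-preserving reallocation
  `w₂ ∝ w₁^θ · exp(η_f u_f + η_p u_p)` (u_f: trait distance to centroid,
  u_p: mean phylogenetic distance), with (θ, η_f, η_p) solved by
  multi-start least squares so realized Simpson/FDis/MPD changes match the
  true rates — typically to well under 1%, always within the 10% the tests
  demand, else an infeasible-target error. Stems realize the target
  basal areas exactly (equal-diameter stems per species); species under
  the single-10-cm-stem floor keep one minimal stem and the remainder is
  rescaled so the plot total is conserved, keeping stand basal-area change
  independent of community structure.
- **Soils**: nine variables (eCEC, Mg, N, P, pH, Fe, Ca, %Clay, %Sand)
  generated from three latent factors — nutrients, acidity–calcium,
  texture — plus proportional noise; with the noise off the covariance is
  exactly rank 3. Texture percentages are kept in [0, 100] with sum ≤ 100.

**What passing tests do and do not show.** The generator has no
demography (recruitment, growth, mortality), no spatial structure, no
observation error in species identification, and its rate–driver coupling
is linear by construction. Recovery results therefore validate the
*pipeline* — that the metrics, null models, grouping and Bayesian machinery
detect a drying signal of realistic size at n = 21 — not any claim about
real forests.

## Reproducibility and problem sizes

Every source of randomness derives from one top-level seed through named
substreams (SHA-256 of the stage name mixed into the seed sequence), so
whole runs are bit-identical. The shipped acceptance checks use the study's
design size (21 plots) throughout; replicate ensembles use 40–50 worlds,
and LOO refits inside large ensembles run at a reduced MCMC budget (2
chains of a few hundred iterations), which leaves selection decisions
unchanged because model ELPD differences are an order of magnitude larger
than the Monte-Carlo error.

## Known limitations

- Exact-refit LOO scales as n·(models); it is the right tool at n ≈ 21 but
  an importance-sampling approximation would be preferable for hundreds of
  observations.
- The SPEI mirrored-fit fallback departs from the canonical construction
  for left-skewed months; real P − PET climatologies are right-skewed and
  rarely trigger it.
- The trait table must cover all species being scored; coverage shortfalls
  are reported per trait (warning below 90% of basal area) but not imputed.
- `ses(MPD)` requires at least two plots and species occurring in more
  than one plot; degenerate matrices yield missing values, not errors.
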