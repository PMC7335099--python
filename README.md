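# forestdiv

Multidecadal change in the functional, taxonomic and phylogenetic diversity
of repeat-census tropical-forest plots along a climatic water-deficit
gradient — as a tested, reusable pipeline.

## Who this is for

Community ecologists with two-census plot data (stem tables with species and
DBH), a species trait table, an ultrametric phylogeny and monthly climate
series who want to ask: *have the facets of diversity shifted over decades,
and are those shifts coupled to drying?* The package also ships a
synthetic-data generator with known ground truth, so the entire analysis can
be exercised and validated without any external data.

## What it computes

**Diversity per plot census** (species weighted by relative basal area
`a_j`, each stem contributing π(DBH/200)² m²):

- Functional dispersion `FDis = Σ a_j z_j / Σ a_j`, where `z_j` is the
  distance of species *j* to the abundance-weighted centroid in trait space
  (z-scored numeric traits; mixed traits through Gower dissimilarity and a
  principal-coordinates embedding). Rao's quadratic entropy
  `Q = Σᵢ Σⱼ aᵢ aⱼ dᵢⱼ` is computed alongside.
- Simpson diversity `1 − Σ Pᵢ²` and its Hill-number form `1/Σ Pᵢ²` (q = 2).
- Abundance-weighted mean pairwise phylogenetic distance (MPD), mean
  nearest-taxon distance (MNTD) and root-inclusive Faith's PD, plus a
  frequency null model (species abundances shuffled across occupied plots)
  giving `ses(MPD) = (obs − null mean)/null sd`. Blomberg's K with a
  999-permutation tip-shuffle test quantifies trait phylogenetic signal.

**Climate drivers per plot** from monthly precipitation, PET and VPD
(1964–2013): the cumulative climatological water deficit
`WDₘ = min(0, WDₘ₋₁ + Pₘ − PETₘ)` reset at the wettest month; MCWD as the
mean of yearly minima over the 30-year windows 1964–1993 (T1), 1984–2013
(T2) and the full 1964–2013 term; 12-month SPEI (L-moment log-logistic);
mean VPD; and absolute changes `ΔX_Abs = X_T2 − X_T1`.

**Inference**, statsmodels-style (a Model you build from data, a Results
object with draws, HDIs and a `summary()`):

- `RobustTwoGroupModel` — annual change rates `ΔX_r = (X_T2 − X_T1)/Δt`,
  split into dry (MCWD_T1 ≤ −250 mm) and wet plots, compared with a
  Student-t (BEST-style) Bayesian model; reports the posterior of
  μ_dry − μ_wet with 50/89/95% HDIs and the probability of direction.
- `BayesianLinearModel` — Gaussian regressions of each rate on climate
  changes, soil principal components and plot area (35 candidate models,
  correlation-pruned drivers at |r| > 0.7), selected by exact leave-one-out
  cross-validation (LOOIC = −2·ELPD) and summarized with per-coefficient
  median, HDIs, ROPE and split-R̂.

## Worked example

One command simulates a 21-plot world with a drying gradient and runs the
full analysis:

```bash
forestdiv run -o run --seed 7
```

which prints (excerpt of the real output):

```
## Dry vs wet group comparison (difference = dry - wet)
  fdis     median diff -1.919e-04  89% HDI [-2.666e-04, -1.172e-04]  Prob 99.9%
  mpd      median diff -8.892e-04  89% HDI [-1.257e-03, -4.965e-04]  Prob 99.8%
  simpson  median diff -2.410e-04  89% HDI [-3.233e-04, -1.476e-04]  Prob 100.0%

## Model selection for d_fdis_r (top 5 by LOOIC)
  looic   -326.01  elpd_diff   0.000  r2_adj  0.539  d_fdis_r ~ d_mcwd_abs + plot_area
  ...

## Best-model coefficients (median, 89% HDI, ROPE, Rhat)
  d_fdis_r     d_mcwd_abs     1.049e-04  [ 6.774e-05,  1.386e-04]  ROPE 0.00  Rhat 1.00
```

Reading it: dry-forest plots lost functional diversity about 1.9×10⁻⁴
FDis-units per year faster than wet plots, and 99.9% of the posterior mass
puts that difference below zero. Model selection picks the regression with
the MCWD change as driver; its coefficient is positive (smaller water-deficit
loss → less diversity loss) with a ROPE of 0.00, i.e. essentially no
posterior mass in the negligible-effect band — which is exactly the
structure the generator built into this world (a positive
ΔMCWD_Abs → ΔFDis_r coupling with drier plots drying fastest).

Each stage is also exposed on its own (`forestdiv simulate`, `diversity`,
`phylo`, `climate`, `rates`, `compare`, `drivers`, `report`) and as library
functions (`forestdiv.fdis`, `forestdiv.mpd`, `forestdiv.climate.mcwd`,
`forestdiv.RobustTwoGroupModel`, ...).

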