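# Methods

This note documents the models, estimation procedures, default
parameters, and numerical choices in `foveometrics`, and the scope and
limitations of the synthetic generators.

## 1. The foveal contour model

The ILM height above Bruch's membrane on one side of the pit centre is
modelled as an asymmetric difference of Gaussians (DoG). With
`d = |x| ≥ 0` the lateral distance from the pit centre (µm) and side
`s ∈ {nasal, temporal}`:

```
h_s(d) = B + A_para,s · exp(−d² / 2σ²_para,s) − A_pit,s · exp(−d² / 2σ²_pit,s)
```

- `B` — shared baseline retinal thickness (µm), common to both sides.
- `A_pit,s ≥ 0`, `σ_pit,s` — depth and width scale of the pit Gaussian.
- `A_para,s` (signed), `σ_para,s` — parafoveal mound. A **negative**
  `A_para` means the parafovea dips below the baseline ("inverted"
  parafovea), an immature configuration; positive means the usual mound.
- Identifiability constraint: `σ_pit,s < σ_para,s` (the pit is narrower
  than the mound). Fits that violate it after optimisation are relabelled
  when the swap is consistent, otherwise flagged `degenerate`.

Both sides share `B` and are coupled through a pit-bottom penalty
(below), so a fitted contour is continuous at `d = 0`. Consequently only
generating truths satisfying `B + A_para − A_pit` equal across sides
describe a continuous contour and are exactly recoverable; the synthetic
generators document and enforce this.

### Analytic derivatives

With `g(d) = exp(−d²/2σ²)`:

```
g′  = −(d/σ²) g
g″  = (d²/σ⁴ − 1/σ²) g
g‴  = (3d/σ⁴ − d³/σ⁶) g
```

All morphometry uses these closed forms; no numerical differentiation of
the fitted contour is ever performed (finite differences appear only in
tests, as independent oracles).

## 2. Fitting

`fit_dog` solves a bounded nonlinear least-squares problem over the joint
9-parameter vector `[B, nasal(A_pit, σ_pit, A_para, σ_para),
temporal(...)]` with `scipy.optimize.least_squares` (Trust Region
Reflective):

- residuals: per-sample model-minus-data on each side, plus one penalty
  row per side, `√λ · (h_s(0) − h_obs(0))`, with `λ = 10`
  (`pit_penalty_weight`) and `h_obs(0)` the observed pit-bottom height.
  The penalty ties both sides to the same pit bottom without hard
  constraints.
- analytic Jacobian (validated against finite differences in tests);
  `x_scale="jac"`, `ftol = xtol = gtol = 1e-10`, `max_nfev = 2000`.
- bounds: `σ ∈ [20, 5000]` µm, `|A| ≤ 1000` µm (`A_pit ≥ 0`),
  `B ∈ [0, 2000]` µm.
- seeded multistart: 5 starts (`n_multistart`), the data-driven initial
  guess jittered by ±30% (`jitter_frac`) with
  `numpy.random.default_rng(seed)`; best final cost wins. Deterministic
  for a given seed.
- at least 20 samples per side are required (`min_samples_per_side`),
  otherwise `InsufficientDataError`.

Measured accuracy (test suite): noise-free recovery of all 9 parameters
< 0.1% relative; < 5% under 2 µm Gaussian noise, with residual norm
consistent with the noise level.

## 3. Morphometry

Six parameters are derived from the fitted contour:

- **Rim edge** (per side): `d* = argmax h‴_s(d)` on `(0, 3000]` µm — the
  point of maximal change of curvature marks the pit rim. A 1 µm grid
  brackets the maximum; bounded scalar minimisation (`minimize_scalar`,
  tolerance 10⁻⁶ µm) refines it. If the argmax falls on either end of the
  grid there is no interior maximum and `RimNotFoundError` is raised.
  For a lone-pit contour (`A_para = 0`) the rim has the closed form
  `d* = σ_pit √(3 + √6) ≈ 2.3344 σ_pit` (root of
  `d⁴ − 6σ²d² + 3σ⁴ = 0`), which the tests verify to 1 µm.
- **Width** = `d*_nasal + d*_temporal` (µm).
- **CFT** (central foveal thickness) = `h(0)` from the fitted contour
  (µm); the raw pit-bottom sample is reported alongside as `cft_raw`.
- **Depth** = mean of the two rim heights minus CFT (µm).
- **Area** = area between the rim-to-rim chord and the contour (µm²).
  The contour integral is exact:
  `∫ A·exp(−d²/2σ²) dd = A·σ·√(π/2)·erf(D/σ√2)`; the chord part is a
  trapezoid in closed form. Tests verify against a 0.05 µm trapezoid
  oracle to 0.1%.
- **Steepest slope** (per side) = `max |h′_s(d)|` on `(0, d*]`, in µm/µm
  and degrees. Lone-pit closed form: maximum at `d = σ`, value
  `A/(σ√e)`.
- **pRT** (per side) = fitted `h_s(1000 µm)`; reported as missing when
  the measured profile does not extend 1,000 µm on that side.

**Parafoveal classification**: the sign of the fitted `A_para` per side —
`inverted` if `A_para < −1` µm, `noninverted` if `> +1` µm,
`indeterminate` inside the ±1 µm dead zone (an amplitude smaller than
any plausible measurement precision should not be classified).

## 4. B-scan preprocessing

The synthetic B-scan is a three-band model: vitreous (intensity 25),
inner tissue (110), and two bright bands (220, half-width 1.5 px) at the
ILM and Bruch's membrane, Gaussian-blurred (σ = 1 px) with optional
multiplicative log-normal speckle. Default geometry: 500 columns × 512
rows, 20 µm/px lateral, 2,000 µm axial depth (≈3.9 µm/px), Bruch at
row 400 with an optional linear tilt.

- **Bruch detection**: per column, intensity threshold at
  `lo + 0.75·(hi − lo)` (1st/99th percentiles); the deepest contiguous
  bright run is taken as the Bruch band and localised to sub-pixel
  precision by the *half-maximum edge midpoint*: the band's rising and
  falling half-maximum crossings are found by linear interpolation and
  averaged. This estimator is unbiased for a blurred symmetric band even
  when it sits on an asymmetric step background (a centroid or parabolic
  peak is not — both are pulled toward the brighter tissue side).
  Columns that fail are interpolated from neighbours; > 50% failures
  raise `SegmentationError`.
- **Flattening**: integer per-column vertical shifts to bring Bruch to a
  reference row (edge-value padding); integer shifts avoid resampling
  the image. Idempotent to ±1 px.
- **ILM segmentation**: per column of the flattened image, the vitreous
  level is the median of the top rows; the first crossing of
  `vitreous + 0.5·(tissue_hi − vitreous)` locates the ILM band, whose
  peak is then refined with the same half-maximum-midpoint estimator.
  A median filter (window 5) plus a max-jump rule (5 px) suppress and
  interpolate outliers. Manual `overrides=[(col, row)]` are applied
  last. Output is a pixel-unit `ILMProfile` of height above the
  reference row. Measured accuracy: ≤ 1 px RMSE noise-free, ≤ 2 px under
  15% speckle.
- **Foveal slice selection**: in a volume (≥ 11 slices) the slice
  minimising central ILM height wins, ties broken toward the volume
  centre; candidates within 5 slices of either end raise
  `InsufficientContextError` (the true minimum may lie outside the
  volume).
- **Micron conversion**: lateral scale × a per-visit correction factor
  for infant axial length (a `CorrectionTable` keyed by rounded
  PMA/GA weeks; missing entries raise `CorrectionLookupError`, never a
  silent default). The profile is re-centred so `x = 0` is the pit
  bottom, localised by a quadratic vertex fit over ±5 samples.

## 5. Cohort statistics

`FovealTrajectoryModel(table, response)` fits, via
`statsmodels` `MixedLM` (REML), the formula

```
response ~ pma_c [+ I(pma_c**2)] + C(rop, Treatment('absent'))
           + pma_c:C(rop, ...) + ga_c (or bw_c100)
           + C(sex) + C(ethnicity) + C(birth) + C(eye) [+ C(side)]
```

with a per-infant random intercept. `pma_c` is PMA centred at 32 weeks,
so the intercept is the predicted 32-week mean; `ga_c` is GA centred at
its sample mean; `bw_c100` is birthweight in 100 g units. GA and BW are
collinear by design and are **never** entered in the same model
(`adjustment="ga"` or `"bw"`). Sided responses (wall slope, pRT) are
melted to long form with a `side` factor. At least half the infants must
contribute ≥ 2 visits, otherwise `InsufficientDataError`.

Derived results:

- `slope_by_rop()` — PMA slope per ROP group with standard errors from
  the fixed-effects covariance (`Var(b_pma) + Var(b_int) + 2Cov` for the
  ROP-present group).
- `predict_means(profiles)` — Wald predicted means and 95% CIs at
  covariate profiles; unspecified factors default to the sample mode,
  unspecified covariates to the sample mean; out-of-range PMA values are
  flagged `extrapolated`.
- `predicted_ratio(p1, p2)` — percentage ratio of two predicted means,
  rounded half-up. The ratio is invariant to rescaling the response.
- `cohort_accounting(CohortCounts)` — exclusion/subgroup percentages
  with enforced identities (`unanalyzable + cystic + analyzed ==
  recruited`; `never + always + mixed == analyzed`) and half-up
  rounding (`floor(x + 0.5)`), the convention that reproduces 3 of the 4
  published accounting figures; the fourth (57/87 printed as 65%) is not
  reproducible under any standard nearest-integer rule (57/87 = 65.52%
  → 66) and is deliberately surfaced as a red acceptance test rather
  than special-cased.
- `chi_square_2x2` — Pearson chi-square without continuity correction
  (`scipy.stats.chi2_contingency`); a zero margin raises
  `UndefinedTestError`.
- `rop_interaction_rejection_rate` — Monte-Carlo type-I error of the
  ROP×PMA Wald test under a null cohort (both groups share slope and
  intercept): 500 seeded replicates at n = 40 single-eye infants by
  default (~1 minute); measured rate ≈ 0.04–0.05.

## 6. Synthetic generators: scope and limitations

All generators are seeded with named, independent
`numpy.random.default_rng([seed, stream])` streams (profile = 1,
B-scan = 2, cohort = 3): changing one stage's draws never perturbs
another's.

- **Profiles** (`gen_ilm_profile`): exact DoG samples plus i.i.d.
  Gaussian height noise on a uniform lateral grid (default 500 points
  over ±5,000 µm). No axial noise, no missing samples, no motion
  artefacts.
- **B-scans** (`gen_bscan`): the three-band model above. It omits inner
  retinal layering, vessel shadows, real speckle correlation, and
  curvature of Bruch's membrane beyond a linear tilt — sufficient to
  exercise and validate the segmentation chain against exact band
  positions (returned as `BScanTruth`), not to imitate an OCT device.
- **Cohorts** (`gen_cohort`): per-infant linear width-versus-PMA
  trajectories whose group slopes/intercepts default to published
  values (−11.18 / +24.96 µm per week; 1,584.9 / 1,203.6 µm at
  32 weeks), Gaussian random intercepts between infants (SD 150 µm) and
  residual noise (SD 100 µm). The two variance defaults are **not**
  published quantities (the source study does not report them); they
  were chosen a priori as plausible magnitudes and produce standard
  errors of the same order as published ones. Other metrics (CFT,
  depth, area, slope, pRT) follow linear-in-PMA means with
  group-dependent coefficients; quality/cystic exclusions are Bernoulli
  draws. Visits occur at 1–2-week intervals within PMA 31–44 weeks
  (times rounded to 0.01 week *before* the mean is computed, so
  noiseless cohorts are machine-exactly linear).

## 7. Numerical conventions

- Lengths in µm, areas in µm², slopes in µm/µm (and degrees), ages in
  weeks, weights in grams. Percentages are integers, rounded half-up.
- CSV floats are written with `%.17g` and read back with
  `float_precision="round_trip"`: every writer/reader pair round-trips
  bit-exactly.
- The pipeline report's `config_hash` is a SHA-256 digest (16 hex chars)
  of the configuration excluding the output directory.
- Error taxonomy: every failure mode has a named exception
  (`SegmentationError`, `ConvergenceError`, `RimNotFoundError`,
  `CohortValidationError`, `SchemaError`, …), all derived from
  `FoveometricsError`; validation errors name the offending column, row
  or field.
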