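# Methods

This note documents the statistical models, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Detrending

**Smoothing spline.** Ring-width series are annual and evenly spaced, so
the "n-year spline" is implemented as the discrete penalized least-squares
smoother `min ||y − s||² + λ ||Δ²s||²` (second differences), solved as a
pentadiagonal banded system. Its interior frequency response is
`H(f) = 1 / (1 + 16 λ sin⁴(πf))`, so the stiffness

    λ = 1 / (16 sin⁴(π / p))

places the 50% amplitude point exactly at period `p` (default 32 years,
the conventional cutoff criterion for dendrochronological splines). The
response is verified empirically in the tests by smoothing pure sinusoids:
0.5 ± 0.05 at the design wavelength, with interannual (8-yr) cycles
retaining ≥ 80% of their amplitude. Indices are ratios `width / fit`, with
the fitted curve floored at 0.005 mm (half the 0.01 mm measurement
resolution) so zero-width (locally absent) rings stay finite, also under
the later log transform. Ratio (not difference) indices are used for both
methods; the trend model's log response requires them.

**Regional curve standardization.** The regional curve is the arithmetic
mean ring width at each cambial age across all (pith-corrected) series of
a population, unsmoothed by default (an optional spline smoothing of the
curve is available and recorded in `RegionalCurve.smoothing`); one curve
per species × site is the intended usage. Cambial age of ring *i* is
`pith_offset + i + 1`. Ages never observed in the sample (possible when
pith offsets leave gaps) are filled by linear interpolation between
neighbouring observed ages; ages beyond the oldest observed age hold the
last value, and any series requiring that extension is flagged. Dividing
each series by the curve yields indices whose population mean is ~1 by
construction (checked: within [0.95, 1.05] on simulated populations).

**Pith offset.** For cores that missed the pith, the innermost ring arc is
treated as a circular segment: with chord length `L` and arc height `h`,
the radius to the pith is `r = (L² + 4h²)/(8h)` (equivalently the sagitta
formula `h/2 + L²/(8h)`), and the missing-ring count is `r` divided by the
mean of the first five measurable ring widths, rounded half-up. The
formula is property-tested against an independent least-squares circle fit
through the three arc points. Exclusion is strict: more than 10 estimated
missing rings drops the core (10 stays, 11 goes).

**Analysis window.** Series are truncated to years ≥ 1850 *after*
detrending (both methods), so the spline fit and cambial ages use the full
series while the models only see years with climate coverage.

## The mixed-effects engine

All models share one marginal Gaussian likelihood. For tree *i* with
responses `y_i` over (possibly gapped) years:

    y_i = X_i β + Z_i b_i + ε_i,   b_i ~ N(0, G),   ε_i ~ N(0, σ² C_i(φ)),

where `C_i(φ)` has entries `φ^|Δyear|` — calendar-year spacing, so
correlation decays correctly across missing rings. `G` is diagonal by
default; an unstructured 2×2 option exists for models with a single random
slope. With up to 11 selected months a free correlation matrix would be
unidentifiable at these sample sizes, and only random-effect SDs are
interpreted, so the diagonal default is deliberate.

Numerics: each tree's AR(1) structure is removed by the exact O(m) Markov
whitening `e_j = (x_j − ρ_j x_{j−1}) / √(1 − ρ_j²)`, `ρ_j = φ^{Δyear_j}`,
after which the random-effect part is handled by the Woodbury identity on
a q×q system. Fixed effects are profiled by GLS and σ² in closed form,
leaving an optimisation over `(log(sd/σ), atanh φ)` only — by L-BFGS-B
with finite-difference gradients (bounds keep |φ| < 1 and SDs positive),
with a Nelder–Mead polish if the line search stalls near the optimum, and
optional random restarts. Convergence tolerance is 1e-10 (relative) on the
log-likelihood; candidate fits inside the exhaustive enumeration use 1e-9,
and the winning model is always refitted at full tolerance. For the
random-intercept-only models of the selection stage, the whitened
cross-products are cached per φ value, which makes evaluations that move
only the variance-ratio coordinate essentially free; this is what keeps
the 2¹⁵ enumeration around 10–15 minutes on one CPU. Correctness of the
likelihood is asserted against a brute-force stacked multivariate-normal
density (explicitly assembled block covariance) to 1e-8 on hundreds of
random small instances, including REML (which is evaluated at the GLS
fixed effects and equals ML plus the standard `−½log|XᵀV⁻¹X| + p/2·log 2π`
adjustment).

Inference conventions: Wald t-tests with denominator df
`n_obs − n_groups − p` (within-group convention); SEs for variance
parameters from a central-difference Hessian of the profile likelihood on
the transformed scale, delta-method back. Significance stars at
0.05/0.01/0.001. Relative random-effect SDs that hit the lower
optimisation bound (ratio ≤ 2e-4) are reported as exactly 0 with a note —
a singular fit, not an error. `AIC = −2ℓ + 2k`, `BIC = −2ℓ + k·log(n)`
with `n` = total observations (not trees): comparability across models on
identical data is what the selection needs, and the convention is recorded
here because it is a choice, not a given. `k` counts fixed effects,
random-effect SDs, φ (if present) and σ.

Diagnostics cover the standard model checks: variance inflation factors of
the fixed-effect columns (∞ flags exact collinearity), Shapiro–Wilk on
whitened (V^{-1/2}) residuals (flag at p < 0.01; subsampled above the
test's validity range), the OLS slope of |whitened residual| on fitted
values as a heteroscedasticity probe, and the lag-1 autocorrelation of
whitened residuals, which should be ≈ 0 when the AR(1) term is adequate.

## Climate–growth analysis

The lagged design has exactly 15 columns — previous August–December and
current January–October — because rings integrate the previous growing
season's carbon balance and the current season up to the measurement
window. Columns are centred and scaled over the response years actually
fitted (default 1851–2008; the first usable year is the first climate year
+ 1). Per-fit standardization keeps "one SD" interpretable: a coefficient
of 0.1 is a 10% index change per SD of that month's temperature.

Selection fits all `2^m` subsets by ML (criteria comparable across fixed
effects) with random intercept + AR(1) only — slopes enter after selection
— and ranks by BIC. Warm starts propagate each subset's variance optimum
to its supersets; every subset is still fully optimised, and a brute-force
test (64 models, no warm starts) confirms the argmin is unchanged. Ties
break by fewer parameters, then lexicographic bitmask. Non-converged
candidates are flagged and excluded from the argmin. The winner is
refitted by REML with a diagonal random slope per selected month plus the
random intercept.

## Growth-trend analysis

The trend model regresses log RCS indices on calendar year, elevation (m)
and their product, with diagonal tree-level random effects on all four
terms and AR(1) errors, fitted by REML. Uncentred year × elevation-in-m
products are numerically hostile (the three regressors are nearly
collinear), so the fit runs on centred variables and coefficients are
back-transformed (`β₃ = c₃`, `β₁ = c₁ − c₃·ē`, `β₂ = c₂ − c₃·t̄`,
`β₀ = c₀ − c₁t̄ − c₂ē + c₃t̄ē`) with delta-method SEs — the uncentred scale
is where slope magnitudes like β₁ ≈ −0.13 with β₃ ≈ 6e-5 are readable.
Random-effect SDs are reported on the centred scale (a diagonal G is not
invariant under centring, so the two parameterizations are genuinely
different models; the centred one is the better conditioned and is what is
fitted). A test asserts that shifting the year/elevation origins leaves β₃
and all predictions unchanged.

Covariate screening refits the base model by ML with every subset of the
extra tree covariates (height, DBH, crown length, aspect, slope) added as
fixed effects and compares by AIC — AIC rather than BIC because the
screening asks about explanatory power, not parsimony of a final model.
Rows with missing covariates are dropped listwise with a logged count.

Predictions are `exp(β₀ + β₁t + β₂e + β₃te)` at the 0/20/40/60/80/100th
percentiles of the sampled tree elevations (six levels), fixed effects
only by default; `per_tree` mode adds each tree's BLUPs
(`b̂_i = G Z_iᵀ V_i⁻¹ r̂_i`). Back-transformed predictions are positive by
construction; extrapolation beyond the fitted years requires an explicit
flag.

## Crossdating QC

A deliberately simplified quantitative check, not a reimplementation of
the classical software chain: each series is spline-detrended (32-yr), the
leave-one-out mean index chronology is formed, and Pearson correlations
are computed overall and in sliding windows (default 50 years advanced by
25, plus a tail window so the overlap is covered). Windows below r = 0.32
— the conventional flagging threshold — are flagged. Autoregressive
prewhitening and segment-shift testing are out of scope; the tool answers
"is this series plausibly dated", not "where should it move".

## Synthetic data

The generator is the package's study-conditions record; its defaults are
chosen once to emulate an alpine-treeline study and are used as-is by the
tests.

Climate: monthly means follow a seasonal cycle `1 + 9·cos(2π(m−7)/12)` °C
(≈ +10 °C July, −8 °C January — a treeline-altitude cycle), plus white
noise with SD 1.0 °C (typical interannual variability of monthly means),
plus a piecewise-linear warming ramp starting in 1950 with per-month
slopes peaking in June at 0.033 °C/yr (≈ +1.9 °C by 2008) and small in
winter/fall — reproducing the observed pattern of a mid-century onset,
June-dominated warming. Years 1850–2008.

Growth is generated multiplicatively:

    log RW_jt = log RC(age) + Σᵢ (βᵢ + b_ij)·T̃ᵢₜ + [trend terms] + b₀ⱼ + ε_jt

with `RC(age) = a·e^{−age/τ} + c` (defaults 2.0 mm, 60 yr, 0.3 mm — a
juvenile peak declining to a mature background, typical conifer
magnitudes), AR(1) ε (φ = 0.5, σ = 0.15 for the climate-growth presets)
and widths rounded to 0.01 mm last, so rounding noise is part of every
recovery budget. The log-additive form is the single generative bridge
between the two analysis scales: for small effects the spline index is
≈ 1 + effects (the additive climate model), while the RCS/log route sees
the same effects exactly. Trend terms use uncentred year and elevation
with the balancing intercept `β₀ = −(β₁t̄ + β₂ē + β₃t̄ē)` so the index
scale stays near 1; tree-level trend deviations are drawn on centred
scales. The `larch_like` preset encodes the larch-type seasonal response
(strong positive July at 0.25 with a deliberately small among-tree SD of
0.03, positive previous fall, negative spring and late summer, SDs 0.08);
`trend_paper_scale` encodes the published-table trend magnitudes
(β₁ = −0.13, β₂ = −0.12, β₃ = 6e-5 over 2250–2540 m, 90 trees, φ = 0.6,
σ = 0.25, random-intercept SD 0.084).

Known mismatches with real data, hence what passing tests do *not* show:
rings formed before 1851 carry no climate effect (no climate exists for
them; they are discarded by the ≥ 1850 truncation before modelling, so
only spline edge behaviour is touched); temperatures are independent
across months apart from the shared warming ramp, where real monthly
temperatures co-vary; there is no precipitation, disturbance, masting, or
size-dependent sensitivity; establishment is uniform in time rather than
climate-driven; and the stand generator couples height to age linearly.
Recovery results on this generator demonstrate estimator correctness under
the assumed model, not robustness to ecological confounding.

Two generator properties surfaced by the end-to-end tests are worth
stating. First, ratio detrending removes each tree's own level, so a
log-scale random intercept largely cancels from spline indices — fitted
intercept SDs near zero on pipeline data are expected, and the
random-intercept recovery tests therefore use model-scale simulation.
Second, spline detrending attenuates climate coefficients by the
fraction of predictor variance it removes (measured ≈ 8% against a
no-detrending oracle fit, bounded < 15% in the tests for white-noise
predictors); for sharply-estimated coefficients this bias exceeds 3
sampling SEs, so pipeline-recovery tests allow max(3 SE, 15%·|β|), while
model-scale recovery uses the strict 3-SE band. When the climate carries
the warming ramp, trended months attenuate more (the spline removes
exactly the low-frequency growth response), which is a real property of
the method, not of the implementation.

## Problem sizes

The test suite and the acceptance script scale the studies to: recovery
suites at 60 trees × 100–120 years (10–20 seeds), trend fits at 90 trees ×
150 years, selection at 2⁸–2¹⁰ candidate subsets with the 2¹⁵ count
verified by enumeration, the likelihood oracle at ≤ 4 trees × ≤ 6 years
(100–200 instances), and pith geometry at 1000 random chord/height pairs.
These sizes were chosen as the smallest at which the properties under test
are statistically sharp.

## Limitations

- The AR(1)-with-gaps covariance assumes the process continues through
  missing years; truly absent rings (not just unmeasured) would need a
  state-space treatment.
- Wald inference with the within-group df convention is approximate;
  p-values on variance components are not provided at all (their nulls sit
  on the boundary).
- REML criteria are not compared across different fixed-effect structures
  anywhere in the package (selection is ML-only), and model averaging is
  deliberately absent.
- The crossdating module flags, but does not correct, dating errors.
- One regional curve per population assumes a shared age trend; strongly
  heterogeneous growth habits within a site would bias RCS indices.
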