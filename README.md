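# dendrogrowth

Statistical analysis of climate–growth relationships and long-term growth
trends of trees at the alpine treeline, built for dendroecologists who work
with individual-tree ring-width series rather than population chronologies.

At treeline, temperature limits radial growth, but individual trees differ
in *when* and *how strongly* they respond — among-tree variability that
population-mean chronologies hide. This package models it explicitly:

- **Detrending** (`dendrogrowth.detrend`). Raw ring widths (0.01 mm
  resolution, Tucson/RWL files) become dimensionless ring-width indices
  (RWI) either by a cubic-type smoothing spline with 50% amplitude response
  at a 32-year period (isolating interannual variability) or by regional
  curve standardization (RCS, dividing by the population's mean
  width-at-cambial-age curve, preserving multi-decadal trends). Cores that
  missed the pith get a geometric missing-ring estimate from the innermost
  ring's curvature — radius `r = (L² + 4h²)/(8h)` for chord `L` and arc
  height `h`, divided by the mean of the first five ring widths; cores with
  more than 10 missing rings are excluded.

- **Climate–growth models** (`dendrogrowth.climate_growth`). Spline RWI of
  tree *j* in year *t* is modelled as

  `RWI_jt = β₀ + Σᵢ (βᵢ + b_ij) · T̃ᵢₜ + b₀ⱼ + ε_jt`,  `ε_jt = φ ε_j,t−1 + η_jt`

  with 15 standardized monthly mean temperatures (previous August–December,
  current January–October) as candidate predictors, a tree-level random
  intercept, and AR(1) residuals. All 2¹⁵ = 32,768 fixed-effect subsets are
  fitted by maximum likelihood and ranked by BIC; the winner is refitted by
  REML with a diagonal random slope for every selected month. Because
  predictors are standardized, a coefficient of 0.1 reads as a 10% change
  in ring-width index per +1 SD of that month's temperature, and the random
  slope SDs quantify among-tree variability on the same scale.

- **Growth-trend models** (`dendrogrowth.trend_model`). Log RCS indices are
  regressed on calendar year, elevation (m a.s.l.) and their interaction,
  with tree-level random intercept and slopes and AR(1) errors:

  `log(RWI_jt) = β₀ + (β₁+b₁ⱼ)t + (β₂+b₂ⱼ)elev + (β₃+b₃ⱼ)t·elev + b₀ⱼ + ε_jt`.

  Predictions are drawn at the 0/20/40/60/80/100th percentiles of the
  sample elevations, from the fixed effects alone or per tree via BLUPs.

- **LMM engine** (`dendrogrowth.lmm_core`). The mixed models above are
  estimated from the marginal Gaussian likelihood written by hand: exact
  AR(1) whitening per tree, Woodbury handling of the random effects, GLS
  profiling of fixed effects and residual variance, ML/REML, Wald tests,
  information criteria, and diagnostics (VIF, Shapiro–Wilk,
  heteroscedasticity slope, whitened-residual autocorrelation). The
  likelihood is verified against a brute-force stacked multivariate-normal
  oracle to 1e-8.

- **Stand structure** (`dendrogrowth.stand_structure`) and **synthetic
  data** (`dendrogrowth.synthetic_data`): elevation-class summaries,
  age–height regression, height→age→ingrowth-time conversion and densities;
  and a generator producing complete synthetic studies (monthly climate
  with a post-1950 warming break, ring-width series with known climate and
  trend effects, stand tables) with the ground truth recorded for recovery
  testing.

## Worked example

```bash
# 1. generate a synthetic larch-like study (60 trees, climate 1850-2008)
dendrogrowth simulate --preset larch_like --seed 42 --out demo/
# -> wrote 60 series, 497 stand trees to demo

# 2. detrend with the 32-yr spline, truncate to >= 1850
dendrogrowth detrend --rwl demo/rings.rwl --method spline --out demo/rwi.csv
# -> wrote 60 detrended series to demo/rwi.csv

# 3. exhaustive BIC selection over 8 hypothesized months (2^8 = 256 fits)
dendrogrowth select --rwi demo/rwi.csv --climate demo/climate.csv \
    --candidates "prevAug,prevSep,prevOct,curFeb,curApr,curJun,curJul,curAug" \
    --out demo/sel/
# -> best model: prevAug + prevSep + prevOct + curFeb + curApr + curJun + curJul + curAug
```

`demo/sel/final_fit.csv` then holds the REML refit, one row per term:

```
     term  estimate     se       p stars  re_sd
intercept    0.9932 0.0047       0   *** 0.0003
  prevAug    0.1018 0.0105 3.5e-22   *** 0.0796
  prevSep    0.1016 0.0095 2.6e-26   *** 0.0725
  prevOct    0.0972 0.0103   3e-21   *** 0.0781
   curFeb   -0.0991 0.0103   1e-21   *** 0.0786
   curApr   -0.1426 0.0109 4.4e-39   *** 0.0826
   curJun    0.1110 0.0092 4.1e-33   *** 0.0693
   curJul    0.2471 0.0039       0   *** 0.0256
   curAug   -0.1228 0.0087 4.5e-45   *** 0.0652
```

read as: +1 SD of current-July temperature raises the expected ring-width
index by ~0.25 (≈25% of the baseline index 1.0; generating truth 0.25) and
the trees agree closely on it (among-tree SD 0.026), while previous-fall
warmth helps (~+0.10 each month, but with among-tree SDs of ~0.07–0.08 —
i.e. as large as the fixed effects themselves) and late-winter/spring and
August warmth depress growth. The selection table
(`selection_table.csv`) lists every candidate subset with its BIC and
ΔBIC, and `diagnostics.txt` reports the model checks. (With all 15
candidates the enumeration fits 32,768 models — about 10–15 minutes on one
CPU.)

The trend side runs analogously from an RCS-detrended index file (the pith
table carries the missing-ring estimates and the series→tree mapping):

```bash
dendrogrowth simulate --preset trend_paper_scale --seed 7 --out tdemo/
dendrogrowth detrend --rwl tdemo/rings.rwl --method rcs \
    --pith tdemo/pith.csv --out tdemo/rwi.csv
# -> pith exclusion: kept 90, excluded 0
dendrogrowth trend --rwi tdemo/rwi.csv --meta tdemo/tree_meta.csv --out tdemo/fit/
# -> trend coefficients: {'beta0': 293.87, 'beta1': -0.14732,
#    'beta2': -0.12433, 'beta3': 6.2329e-05}
```

(generating truth: β₁ = −0.13, β₂ = −0.12, β₃ = 6e-5). A positive
time × elevation interaction against a negative time main effect means the
log-scale growth trend `β₁ + β₃·elev` flips sign within the sampled
gradient: declining indices at the low end, rising towards the treeline.
`tdemo/fit/trend_predictions.csv` holds the back-transformed index
predictions at the 0/20/40/60/80/100th elevation percentiles.

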