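# Methods

This note records the model, the numerical choices, what the synthetic-data
generator does and does not emulate, and the main design decisions.

## 1. The steady-state branch-point model

### Enzymes and expression

Four pathway genes are modeled: tHMGR (pathway supply), FPPS\* (the mutant
FPP synthase that releases GPP), LIS (linalool synthase) and GES (geraniol
synthase). Measured abundances are relative; per-gene conversion factors
`alpha_H, alpha_F, alpha_L, alpha_G` map them to effective enzyme levels
`E_H, E_F, E_L, E_G`. This makes the absolute scale unidentifiable by
construction: multiplying all alphas by `c` while dividing `v_H` and the
kcats by `c` leaves every prediction unchanged (a property the tests assert).

### GPP balance

Supply is treated as zeroth-order in upstream metabolites (saturating
substrate): `supply = v_H · E_H · θ`. The cell contains endogenous FPP
synthase (abundance `β·E_F`) alongside FPPS\* (abundance `E_F`); `θ` is the
abundance-weighted mean of the per-enzyme GPP release fractions,

```
θ = (rho_star + rho_wt·β) / (1 + β),   rho_star > rho_wt,
```

which is independent of `E_F` itself. With `E_F = 0` supply routes through
the endogenous enzyme at `rho_wt`; with `β = 0` the pool is pure FPPS\* at
`rho_star`.

Consumption sums three Michaelis–Menten branches plus first-order loss:

```
C(G) = kcat_L·E_L·G/(K_L+G) + kcat_G·E_G·G/(K_G+G)
     + kcat_F2·(1+β)·E_F·G/(K_F+G) + k_d·G
```

`C` is strictly increasing, so `supply = C(G)` has a unique root. A
consequence worth flagging: raising FPPS\* abundance does **not** raise `θ`
(which depends only on `β`), but it does add GPP consumption through the FPP
branch, so in this model FPPS\* abundance alone is neutral-to-negative for
monoterpene titers. Production gains from FPPS\* come through `rho_star` and
`β`, not through `E_F`. The worked example's correlation report shows this:
FPPS\* abundance has no positive correlation with total production even
though the mutant enzyme is essential for any production at all.

### Numerics

The scalar solver uses Brent's method on the exact bracket
`[0, supply/k_d]` (when `k_d > 0`; otherwise a doubling search, with a
`NoSteadyStateError` if total saturable capacity cannot absorb the supply),
relative tolerance 1e-12. The fitting hot path uses a vectorized 120-step
bisection over strain batches, which matches the scalar solver to well below
1e-9 relative and makes one cost evaluation on an 18-strain panel ~1.5 ms.
Both are checked against an independent dense-grid + bisection oracle in the
tests.

### Titers

Predicted titers are the synthase fluxes times a common yield factor
`yield_T` (mg/L per flux unit), absorbing culture volume, time and export.

## 2. Reference predictors

- **Log-linear**: per-monoterpene OLS of `log10(titer + 0.01)` on the four
  `log10(abundance + 1e-3)` plus intercept (10 coefficients total). Exact on
  its own family; a rank-deficient design raises an error naming the
  collinear genes.
- **Smooth**: per-monoterpene Gaussian-process regression (fixed
  constant×RBF kernel, default length scale 1.0 in log-abundance space,
  `normalize_y`, no hyperparameter optimization) so predictions revert to
  the training mean far from data and the fit is deterministic.

Models are compared by leave-one-out cross-validation on replicate-mean
titers; kinetic refits inside LOO are seeded per fold (base seed + fold
index) for reproducibility.

## 3. Fitting

Differential evolution (rand/1/bin, F = 0.7, CR = 0.9, population 15 per
free parameter, up to 300 generations with a 50-generation stall stop at
1e-10, final local polish), seeded. Default free parameters are the four
alphas, `β` and `yield_T`; bounds are one decade centered in log space on
the nominal values. The cost is the sum of squared residuals of replicate-
mean titers in linear space (log10 space is available). Because of the
scaling degeneracy above, recovery is judged on predicted titers, not on
raw parameter values.

## 4. Synthetic-data generator

The generator emulates a strain-panel experiment with a known ground truth:

- **Expression**: abundance = gain · (0.05 + promoter strength) ·
  LogNormal(0, cv), i.e. basal leakage 0.05 plus a linear promoter effect,
  with multiplicative replicate noise (default protein CV 0.2). Promoter
  strength is normalized catalog rank; the default catalog has 8 promoters.
- **Titers**: kinetic-model prediction times LogNormal(0, cv) per replicate
  (default titer CV 0.15, 3 replicates).
- **Sugars**: a 90 g/L wort (15 maltotriose / 65 maltose / 10 glucose);
  total pathway burden linearly raises the residual-sugar fraction
  (slope 0.2), and ethanol is 0.46 g/g of consumed sugar.
- **Hop variation**: replicate titer sets (within-CV 0.05) vs
  hop-preparation sets (5 preparations, between-CV 1.0). The between-
  preparation CV of 1.0 reflects the order-of-magnitude spread reported for
  essential-oil content between hop lots; at these sample sizes the
  deviation-based test statistic is scale-free, so detection power depends
  on the CV ratio, not on the absolute titers.
- **Growth**: logistic OD curves with an explicit lag, additive Gaussian
  noise, floored at 1e-6.

Not emulated: fermentation dynamics over time (only endpoints), glycoside
precursors in wort, sensory response, plasmid/copy-number effects, and any
interaction between monoterpene production and growth rate.

## 5. Metrics and design evaluation

- **Scaling**: min–max on log10 after flooring (0.01 mg/L titers, 0.01 g/L
  sugars); residual fermentable sugars are inverted so 1 means fully
  consumed; ethanol is not inverted. A zero range is an explicit error.
- **Growth rate**: maximum slope of ln(OD) over sliding windows spanning at
  least 5 h (windows defined by time span, advancing one sample), clamped
  at 0.
- **Distance to a target beer**: mean of |Δlog10 linalool|,
  |Δlog10 geraniol| and the residual-sugar fraction. A ten-fold titer miss
  adds 1/3; an unfermented wort adds 1/3.
- **Design policies**: "random" draws every promoter uniformly;
  "principled" draws strong promoters (strength ≥ 0.67) for tHMGR, FPPS\*
  and GES and any promoter for LIS (strong push on supply and the geraniol
  branch, a strength ladder on the linalool branch). The policy experiment
  samples 18 designs per policy, simulates expression and titers from the
  ground truth, includes the sugar-burden component, and applies a
  one-sided Welch t-test (principled closer than random). Note the two
  dilutions built into this comparison: principled designs carry more
  expression burden (worse sugar component), and extra FPPS\* expression is
  not beneficial in this model (see §1), so measured power is lower than a
  titer-only comparison would suggest.
- **Variance comparison**: primary test is a one-sided Welch t on absolute
  deviations from each set's own mean; the F-ratio is reported as a
  secondary check because it is exact only under normality.

## 6. Problem sizes

Defaults throughout target a single CPU: 18-strain panels with 3
replicates, DE budgets as above (a full kinetic fit ≈ 40 s, pipeline
including LOO ≈ 2–3 min), 50-seed policy replications, 200-seed variance
replications. Tests use scaled-down versions of the same procedures
(fewer free parameters or smaller DE budgets) where the full-size run is
exercised elsewhere.

## 7. Known limitations

- The model's θ/β formulation makes FPPS\* abundance per se non-beneficial;
  if abundance-dependent complex formation mattered in vivo, the principled
  policy would gain an additional advantage not captured here.
- The GP regressor uses a fixed kernel; no hyperparameter search.
- Burden→attenuation is a linear link with a single slope, not a resource
  model.
- Parameters are in arbitrary relative units except titers (mg/L), sugars
  (g/L) and rates (/h); only titer-space predictions are identifiable.
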