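# hopflow

Model-guided design of brewing yeast that makes its own hop flavor.

The two monoterpenes that dominate "hoppy" beer aroma — linalool and
geraniol — can be produced by yeast itself if the strain carries a linalool
synthase and a geraniol synthase fed from the mevalonate pathway. Hitting a
*particular* beer style is harder than making *some* monoterpene: the two
titers must land near the target levels (fractions of a mg/L) while the
strain still ferments wort sugars completely. `hopflow` implements the
design–build–test–learn loop for this problem in silico:

- a steady-state kinetic model of the branch point where geranyl
  pyrophosphate (GPP) is partitioned between linalool synthase, geraniol
  synthase and the competing FPP synthase reaction;
- parameter estimation from strain panels (differential evolution), plus two
  reference predictors (log-linear regression and a Gaussian-process
  regressor) compared by leave-one-out cross-validation;
- a synthetic-data generator (promoter-driven expression, replicate noise,
  sugar attenuation, OD growth curves) with a known ground truth for
  validating every estimator;
- strain scoring against target beer profiles and a quantitative test of
  whether promoter-design heuristics beat random promoter sampling;
- fermentation metrics: min–max log scaling for heatmaps, residual-sugar
  fractions, and sliding-window maximum specific growth rates.

## The model

Each strain carries four pathway genes — a truncated HMG-CoA reductase
(tHMGR), a mutant FPP synthase (FPPS\*) that releases part of its GPP
intermediate, a linalool synthase (LIS) and a geraniol synthase (GES) — each
driven by a promoter chosen from a ranked catalog. Promoter strength is the
normalized rank (weakest 0, strongest 1). At steady state the GPP level `G`
balances supply against consumption:

```
v_H·E_H·θ  =  kcat_L·E_L·G/(K_L+G) + kcat_G·E_G·G/(K_G+G)
              + kcat_F2·(1+β)·E_F·G/(K_F+G) + k_d·G
```

where `θ` is the effective GPP release fraction of the mixed wild-type/mutant
FPP synthase pool and `β` their abundance ratio. The right side is strictly
increasing in `G`, so the root is unique; titers are the synthase fluxes
times a yield factor. See `docs/methods.md` for the full derivation,
parameters and assumptions.

## Worked example

```python
from hopflow import (default_ground_truth, initial_designs, generate_dataset,
                     NoiseModel, generate_targets, correlation_report,
                     predict_titers, ProteinProfile)

truth = default_ground_truth()
designs = initial_designs(truth.catalog, n=18, seed=7)
panel = generate_dataset(designs, truth, NoiseModel(), replicates=3, seed=7)

prof = ProteinProfile("demo", {"tHMGR": 1.0, "FPPS_star": 1.0,
                               "LIS": 0.6, "GES": 0.9})
pred = predict_titers(truth.params, prof)
print(pred.linalool, pred.geraniol)   # 0.5631, 0.8447 mg/L

print(correlation_report(panel))
```

The correlation report on this 18-strain panel recovers the expected
structure: tHMGR abundance correlates with total monoterpene production
(r = 0.83, p = 2.2e-05) and the GES/LIS ratio with the geraniol fraction
(r = 0.95, p = 2.5e-09), while FPPS\* abundance alone shows no positive
total-production correlation (r = −0.15) because in the steady-state model
extra FPPS\* also drains GPP toward FPP.

Scoring the same panel against the mid-intensity target beer (0.2 mg/L of
each monoterpene), the best strain lands at distance 0.151 — components
(0.09, 0.30, 0.065) for the linalool log-error, geraniol log-error and
residual-sugar fraction — i.e. within about 2-fold of both titer targets
with 93% of the wort sugars consumed.

The same loop runs from the command line:

```bash
hopflow run --seed 0 --out-dir results/run0
hopflow report --data-dir results/run0 --out results/run0/report.json
```

which simulates a panel, scales titers, fits the kinetic model, runs LOO
cross-validation, and evaluates principled vs random promoter policies,
writing a byte-reproducible manifest.

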