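# pmfsa — PMF source apportionment for speciated PM2.5

`pmfsa` is a Python implementation of the standard receptor-modeling
chain used to apportion ambient fine particulate matter (PM2.5) among
its emission sources from speciated filter measurements alone — no
emission inventory required.  It is aimed at air-quality scientists who
have a samples × species concentration table (ions, trace elements,
organic/elemental carbon, total mass), per-species method detection
limits, and optionally wind records, and who want a scripted,
reproducible alternative to GUI receptor-modeling tools.

## The model

Measured concentrations **X** (n samples × m species, μg/m³) are
factorized into nonnegative source contributions **G** (n × p) and
source chemical profiles **F** (p × m):

```
X = G F + E,        G ≥ 0, F ≥ 0
```

fit by minimizing the uncertainty-weighted objective

```
Q = Σᵢ Σⱼ (eᵢⱼ / σᵢⱼ)²,     eᵢⱼ = xᵢⱼ − Σₖ gᵢₖ fₖⱼ
```

where σᵢⱼ is the per-cell measurement uncertainty.  Around that core
the package provides:

* **Conditioning** — mass-closure sample screening (±50%), exclusion of
  species ≥90% below detection limit (BDL) or missing, geometric-mean
  imputation of missing cells (uncertainty 4× the mean), MDL/2
  substitution for BDL cells (uncertainty (5/6)·MDL), the measurement
  error model σ = √((0.1·x)² + (0.5·MDL)²), and 4× down-weighting of
  the total-mass column.
* **Diagnostics** — scaled residuals R = E/σ with the ≥80%-within-±3
  adequacy rule; IM/IS curves (max species-wise mean and standard
  deviation of scaled residuals) whose sharp drop locates the factor
  count; R² of reconstructed vs. measured mass.
* **Fpeak rotation** — a scan of the rotational ambiguity of a
  converged solution over φ ∈ [−1, 1] in 0.1 steps, reporting the Q
  penalty of each candidate; choosing the physically meaningful
  rotation is left to the analyst.
* **Contribution reporting** — mass-scaled G aggregated overall, by
  calendar month, and weekday vs. weekend, as means and percentage
  shares.
* **CPF** — the conditional probability function CPF(Δθ) = mΔθ/nΔθ per
  22.5° wind sector (exceedances of the 80th-percentile contribution,
  calm winds ≤1 m/s excluded), which points toward source bearings.
* **Synthetic ground truth** — a generator producing datasets with
  known G, F, censoring, missingness and planted wind bearings, so the
  whole chain is testable end to end.

## Worked example

Apportion a study-scale synthetic campaign (74 daily samples, 30 raw
species columns, 9 true sources, one sample violating mass closure):

```python
import pandas as pd
from pmfsa import (GroundTruth, generate, preprocess, PMFConfig, fit,
                   apply_fpeak, normalize_factors, diagnose, aggregate,
                   cpf_compute)

ds, wind, truth = generate(GroundTruth.study_scale(seed=7))
cm = preprocess(ds, drop_list=("Sn", "Cu", "F-"))   # -> 73 x 25
sol = fit(cm.X, cm.U, PMFConfig(n_factors=9, n_starts=20, seed=42),
          species_names=cm.species_names)
sol = apply_fpeak(sol, -0.1, cm.X, cm.U)
scaled = normalize_factors(sol, "PM2.5")
report = diagnose(cm.X, cm.U, scaled, measured_mass=cm.measured_mass)
overall = aggregate(scaled.G, cm.dates)[0]
```

which prints (via the obvious loops):

```
conditioned: (73, 25) | exclusions: 6
Q = 869.6 (best of 20 starts)
coverage3 = 0.999 | IM = 0.026 | IS = 0.864 | R^2 = 0.900
factor_1    5.04 ug/m3  29.17 %
factor_2    3.07 ug/m3  17.77 %
factor_3    1.94 ug/m3  11.20 %
...
factor_9    0.82 ug/m3   4.73 %
```

The conditioned matrix keeps 73 of 74 samples (one failed mass closure)
and 25 of 30 species (three dropped by the analyst's low-reliability
list, two by the 90% BDL rule).  99.9% of scaled residuals fall within
±3, so the uncertainty model is adequate; R² = 0.90 says the nine
mass-scaled factors explain 90% of the day-to-day variability in
gravimetric PM2.5.  The contribution table is the apportionment itself:
the largest factor carries 5.04 μg/m³ (29% of mass).  A CPF on factor 1
against the generated winds peaks at the 315° (NW) sector — exactly the
bearing the generator planted:

```python
series = pd.Series(scaled.G[:, 0], index=cm.dates)
res = cpf_compute(series, wind)      # peak CPF 0.50 at 315.0 deg
```

The same chain is available from the shell:

```
pmfsa simulate --preset study-scale --seed 7 --out data/
pmfsa preprocess --conc data/conc.csv --mdl data/mdl.csv --out run/
pmfsa scan-factors --x run/X.csv --u run/U.csv --pmin 2 --pmax 12 --out run/curves.csv
pmfsa fit --x run/X.csv --u run/U.csv --factors 9 --fpeak -0.1 --out run/
pmfsa diagnose --run run/
pmfsa contributions --run run/
pmfsa cpf --run run/ --wind data/wind.csv --plot
pmfsa run-all --simulate-preset study-scale --seed 7 --out run/
```

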