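# halex

Life expectancy (LE) and health-adjusted life expectancy (HALE) estimation
for type 2 diabetes mellitus (T2DM) in an elderly cohort, by two
complementary routes:

* **Sullivan method** — a Chiang abridged life table built from an
  age-grouped mortality schedule, with each interval's person-years
  discounted by the cross-sectional disease prevalence:

  HALE(x) = (1/l_x) · Σ_{y≥x} (1 − π_y) · L_y

  where l_x are survivors at exact age x, L_y the person-years lived in
  interval y, and π_y the T2DM prevalence in that interval.

* **Multistate (illness-death) method** — a three-state continuous-time
  Markov model (1 = T2DM-free, 2 = T2DM, 3 = dead; transitions 1→2, 1→3,
  2→3, no recovery) with Gompertz transition intensities
  q_rs(a, z) = exp(α_rs + ξ_rs(a − 65) + β_rs′z), fitted by maximum
  likelihood to two-wave panel data in which disease onset is
  interval-censored and death ages are exact with unknown pre-death state.
  Total and state-specific life expectancies come from numerical
  integration of the occupancy probabilities,
  e_rs(x) = ∫ P_rs(x, x+u) du, so HALE is the expected disease-free time
  e_11 and LE is e_11 + e_12.

The package is aimed at epidemiologists and health demographers who want
both estimators, their uncertainties, and a fully synthetic illness-death
cohort generator to validate the whole pipeline against known truth:
individual-level cohort and surveillance mortality data of the kind these
methods are usually applied to are almost never redistributable, so every
stage here can be exercised on simulated data with the same structure
(baseline ~13% prevalence at ages 65–79, one follow-up wave 2–4 years
later, ~11.5% loss to follow-up).

## Worked example

```python
import numpy as np
from halex import (SimulationConfig, simulate_cohort, IllnessDeathModel,
                   estimate_prevalence)

# prevalence with a Wilson interval from aggregate counts
p, (lo, hi) = estimate_prevalence(5647, 844)
print(f"women baseline prevalence: {100*p:.2f}% (95% CI {100*lo:.2f}-{100*hi:.2f}%)")

# synthetic two-wave cohort -> multistate fit -> life expectancy at 65
records = simulate_cohort(SimulationConfig(cohort_size=10318, seed=1))
results = IllnessDeathModel(records).fit()
for sex, z in [("men", [1.0]), ("women", [0.0])]:
    le = results.life_expectancy(65.0, z=z)
    print(f"{sex:6s} at 65: LE {le.total:5.2f} y, HALE {le.years_in_state[1]:5.2f} y, "
          f"HALE/LE {100*le.years_in_state[1]/le.total:5.2f}%")
```

prints

```
women baseline prevalence: 14.95% (95% CI 14.04-15.90%)
men    at 65: LE 18.59 y, HALE 16.78 y, HALE/LE 90.29%
women  at 65: LE 21.06 y, HALE 16.91 y, HALE/LE 80.28%
```

A 65-year-old disease-free man in this synthetic population expects 18.6
further years, 16.8 of them free of T2DM; women live longer in total but
spend a larger share of remaining life with the disease, so their HALE/LE
ratio is lower — the sex pattern these two estimators are typically used
to quantify. `results.summary()` shows the nine fitted log-intensity
parameters with standard errors;
`results.life_expectancy_ci(65.0, z=[0.0], seed=0)` adds parametric-
bootstrap confidence intervals.

The same pipeline is scriptable from the shell:

```sh
halex simulate --seed 1 --cohort-size 10318 --out panel.csv
halex fit-msm --panel panel.csv --out params.csv
halex pipeline --config config.yaml   # simulate -> life table -> Sullivan -> multistate
```

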