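# boundedmi

Multiple imputation for **bounded event times** in **competing-risks** analyses.

In registry follow-up studies an event of interest is often reported without an
exact onset date: the time is only known to lie in an interval (L, R]. The
motivating setting is acute graft-versus-host disease (aGvHD) after stem-cell
transplantation, where onset competes with graft failure and death, onset dates
are frequently unreported, and a missing time is only known to fall in the
first 100 days. Naive fixes — dropping incomplete cases, substituting the
mean — bias the cumulative incidence and the median onset time.

`boundedmi` is a simulation laboratory for comparing multiple-imputation (MI)
strategies in exactly this setting. It provides:

* a **synthetic registry generator**: competing event types drawn from a
  categorical distribution, log-normal event times in whole days,
  administrative censoring at one year, an auxiliary binary covariate, and
  MCAR / MAR / MNAR missingness mechanisms for the cause-1 times;
* the **Aalen-Johansen estimator** of the cause-specific cumulative incidence
  F_k(t) = Σ_{t_j ≤ t} Ŝ(t_{j−1}) d_kj / n_j with the Marubini-Valsecchi
  Greenwood-style pointwise variance, and a delta-method SE for the median
  time SE(t̂₅₀) = SE(F̂(t̂₅₀)) / f̂(t̂₅₀), where f̂ is a local-gradient
  density estimate around the median;
* five **imputation engines** (scikit-learn style transformers): unrestricted
  normal regression (`NormalImputer`), log-normal regression with
  back-transformation (`LogNormalImputer`), normal regression with rejection
  sampling against the interval bounds (`RestrictedNormalImputer`), type
  0/1/2 predictive mean matching (`PMMImputer`), and CIF-conditional sampling
  of observed times with an iteratively refreshed Aalen-Johansen estimate
  (`CIFSamplingImputer`);
* **Rubin's rules** pooling (T = W̄ + (1 + 1/m)B) and a **Monte-Carlo
  harness** that runs the factorial method × mechanism × missing-fraction
  study and reports standardized bias, (β̄̂ − β)/SD(β̂), and average
  model-based SE, √(Σ SE²/K).

## Worked example

```python
import numpy as np
from boundedmi import (SimulationConfig, MissingnessSpec, generate_dataset,
                       apply_mdm, PMMImputer, AalenJohansenEstimator, rubin_pool)

config = SimulationConfig()                      # n=500, probs .65/.25/.10, ...
data = generate_dataset(config, rng=7)
incomplete = apply_mdm(data, MissingnessSpec("MAR", 0.5), rng=7)

completed = PMMImputer(m=5, random_state=0).fit_transform(incomplete)
fits = [AalenJohansenEstimator(cause=1).fit(d) for d in completed]
pairs = [f.cif_at(100.0) for f in fits]
cif = rubin_pool([p[0] for p in pairs], [p[1] for p in pairs])
meds = [f.median_estimate() for f in fits]
med = rubin_pool([m.median for m in meds], [m.se for m in meds])
print(f"CIF(100): {100*cif.estimate:.2f}% (SE {100*cif.se:.2f}%)")
print(f"median:   {med.estimate:.1f} days (SE {med.se:.2f} days)")
```

prints

```
CIF(100): 62.80% (SE 3.27%)
median:   48.8 days (SE 18.14 days)
```

With half of the aGvHD times missing at random, predictive mean matching
recovers a day-100 cumulative incidence close to the analytic truth of 63.3%,
and a median within one (appropriately wide, imputation-inflated) SE of the
true 44 days. A complete-case analysis of the same incomplete dataset returns
31.70% (SE 2.86%) — more than ten SEs below the truth — because dropping
aGvHD cases leaves the competing events over-represented.

The same pipeline is scriptable from the shell:

```bash
boundedmi simulate --seed 1 --mechanism MAR --fraction 0.5 --out data.csv
boundedmi impute data.csv --method PMM --m 5 --seed 2 --out done
boundedmi estimate done_imp1.csv
boundedmi study --reps 100 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `boundedmi.simulate` | generating mechanism, missingness mechanisms, analytic truths |
| `boundedmi.estimators` | Aalen-Johansen CIF, Greenwood-style SE, median delta-method SE |
| `boundedmi.imputers` | the five MI engines and the posterior-draw regression core |
| `boundedmi.pooling` | Rubin's rules |
| `boundedmi.study` | factorial harness, standardized bias, average model SE, plots |
| `boundedmi.io` / `boundedmi.cli` | CSV/YAML serialization and the `boundedmi` command |

See `docs/methods.md` for the statistical details and design choices.
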