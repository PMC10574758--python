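# carbsafe

In-silico evaluation of **personalized safe limits for carbohydrate-counting
errors** in type 1 diabetes.

People with type 1 diabetes dose mealtime insulin from an estimate of the
carbohydrates they are about to eat, using the standard bolus calculator

```
B = CHO/ICR + (G - G_T)/ISF - IOB
```

(`B` bolus in U, `CHO` estimated grams, `ICR` insulin-to-carbohydrate ratio
in g/U, `G` preprandial glucose, `G_T` the 100 mg/dL target, `ISF` insulin
sensitivity in mg/dL/U, `IOB` insulin on board).  Counting mistakes corrupt
the bolus and push postprandial glucose out of the 70–180 mg/dL band.  How
big a mistake is tolerable is *patient-specific*:

```
dCHO_max = (ICR/ISF) * min(G_H - G_T, G_T - G_L)
```

is the largest absolute counting error (grams) whose bolus error still keeps
the settled (2–3 h) postprandial glucose inside the band.  With the standard
70/100/180 mg/dL thresholds this is `30 * ICR/ISF`.

This package asks: *does that closed-form limit actually behave like a safety
boundary?*  It answers with a virtual clinical trial:

- a 33-subject virtual roster (11 adults, 11 adolescents, 11 children) whose
  personal limits average 9.13 ± 2.99 g (range 5.37–16.55 g);
- a calibrated minimal glucose–insulin metabolic model per patient (Bergman
  core, two-compartment subcutaneous insulin and gut absorption), tuned so
  each patient's realized ISF and exact-dose meal recovery honor their
  therapy parameters;
- a 90-day open-loop basal–bolus protocol, five meals a day (450 meals),
  CGM-sampled every 5 minutes;
- ten experiments: an error-free control `E0` and nine error distributions
  `E1`–`E9` expressed as 95% normal intervals in multiples of `dCHO_max`
  (symmetric, one-sided within the limit, centered on the limit — 50% of
  meals outside — and beyond the limit — 97.5% outside);
- outcome metrics TIR / TAR / TBR (plus % time < 50 and > 300 mg/dL) and
  paired percentile-bootstrap inference of each experiment against `E0`.

## Worked example

```python
import carbsafe as cs
from carbsafe.trial import CarbCountingTrial, TrialConfig

roster = cs.load_reference_roster()
results = CarbCountingTrial(roster, TrialConfig(days=90, master_seed=0)).run()
print(results.summary())
```

prints (seconds for calibration, ~10 s for the 330 patient-experiment cells):

```
Carb-counting error trial: 33 patients, 90 days, experiments E0, E1, E2, E3, E4, E5, E6, E7, E8, E9
Retained after control TIR >= 90%: 33 subjects (always-in-range stratum: 33)

Mean difference vs E0 (tir_90 stratum), percentage points:
 exp      TIR      TAR      TBR     %<50    %>300
  E1    -3.17     0.99     2.18     0.05     0.00
  E2    -2.14     1.98     0.16     0.00     0.00
  E3    -1.06     0.00     1.06     0.00     0.00
  E4    -3.79     3.79     0.01     0.00     0.00
  E5    -1.00     0.00     1.00     0.00     0.00
  E6    -6.46     6.46     0.00     0.00     0.00
  E7    -2.01     0.00     2.01     0.00     0.00
  E8    -9.10     9.05     0.06     0.00     0.00
  E9    -5.83     0.00     5.83     0.00     0.00
```

Reading it: under error-free dosing every calibrated patient stays fully in
range (TIR 100%, nobody excluded).  Counting errors *within* the personal
limit (`E1`–`E5`) cost a few TIR points at most; errors centered on or
beyond the limit (`E6`–`E9`) degrade TIR markedly.  The direction follows
the error sign — underestimation experiments (`E2`, `E4`, `E6`, `E8`) lose
range time upward (TAR), overestimation experiments (`E3`, `E5`, `E7`,
`E9`) downward (TBR) — e.g. `E8` raises TAR by 9.05 points (bootstrap 95%
CI 8.13–9.99) and the mirror design `E9` raises TBR by 5.83 points (CI
4.61–7.01).  `results.outcomes`, `results.comparisons` and
`results.meal_log` hold the tidy tables; `results.save("out/")` writes CSVs,
a manifest and difference-bar figures; the same study is scriptable through
the `carbsafe` CLI (`roster`, `calibrate`, `run`, `report` subcommands).

Re-running with the same master seed reproduces every table byte-for-byte;
each (patient, experiment) cell draws from its own seed sub-stream, so any
slice can be recomputed in isolation.

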