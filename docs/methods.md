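# Methods

## The question

For a patient dosing prandial insulin with the standard bolus calculator,
the personalized safe carbohydrate-counting limit

```
dCHO_max = (ICR/ISF) * min(G_H - G_T, G_T - G_L)
```

is derived from a steady-state argument: a counting error of `e` grams
perturbs the bolus by `e/ICR` units, which shifts the settled (2–3 h)
postprandial glucose by `e * ISF/ICR` mg/dL; the shift reaches the nearer
band edge exactly when `|e| = dCHO_max`.  With the consensus 70/100/180
mg/dL band the hypoglycemia side binds (`min` term = 30 mg/dL), so
`dCHO_max = 30 * ICR/ISF` and an overestimation of exactly `dCHO_max`
parks the 2.5-h glucose at 70 mg/dL.  The package tests whether this limit
behaves like a boundary in a simulated 90-day trial.

## Virtual cohort

The reference roster carries 33 subjects (11 per age cohort; the eleventh is
the population-average subject of each cohort).  The only per-subject
quantity the design depends on is `dCHO_max` (equivalently the ICR/ISF
ratio); individual ICR/ISF pairs for the original simulator population are
not public, so each subject is assigned the cohort-mean ICR (adults 15.9,
adolescents 17.6, children 26.5 g/U) and the ISF that reproduces their
published limit exactly (`ISF = 30 * ICR / dCHO_max`).  Every
Table-derivable statistic of the roster (mean 9.13 g, SD 2.99 g, range
5.37–16.55 g) is preserved by construction.  `generate_cohort` additionally
draws synthetic cohorts from the published cohort-level ICR/ISF summaries
(independent normals, rejection-truncated to mean ± 3 SD and positivity);
the independence of ICR and ISF draws is an acknowledged simplification —
no correlation is published.

## Error model

Each experiment prescribes an interval of counting errors in multiples of
`dCHO_max`, read as the central 95% of a normal law: `mu` is the interval
midpoint, `sigma` the half-width divided by `z = 1.959964` (the exact 97.5%
quantile, fixed for bit-reproducibility).  Draws are untruncated — 5% of
meals intentionally exceed the printed interval — and are absolute grams,
independent across meals, identical in law across meal sizes.  The closed
form for the mass outside `[-dCHO_max, dCHO_max]` gives 5% for the
symmetric design E1, exactly 50% for the limit-centered designs E6/E7 (the
mean sits on the interval edge; the far tail is ~41 sigma away and
numerically zero) and `Phi(z) = 97.5%` for the beyond-limit designs E8/E9.

The source text describes the error once as "uniformly distributed" while
denoting it `N(mu, sigma^2)` and plotting normal densities; this package
implements the normal reading throughout.

## Metabolic stand-in and calibration

Physiology is a deliberately minimal ODE model (Bergman-type core,
two-compartment subcutaneous insulin, two-compartment gut absorption; see
the `simulator` module docstring for the equations).  It is a stand-in: the
claims under test concern dosing-error propagation, not fine physiology.

Template constants, shared by all patients:

| parameter | value | units | meaning |
|---|---|---|---|
| `p1` | 0.003 | 1/min | glucose effectiveness (insulin-independent return to `g_b`) |
| `p2` | 0.09 | 1/min | remote insulin action rate |
| `tau_i` | 50 | min | subcutaneous insulin absorption time constant |
| `i_clear` | 0.1 | 1/min | plasma insulin clearance |
| `bioavail` | 0.9 | – | fraction of meal carbohydrate reaching plasma |
| `g_b` | 100 | mg/dL | fasting equilibrium under basal insulin |
| basal | 1.2 / 1.1 / 0.6 | U/h | cohort default basal infusion (adult/adolescent/child) |

Three parameters are calibrated per patient by bounded bisection
(deterministic, each stage bracket-checked):

1. **`si` (insulin action gain)** — a correction bolus sized to span the
   target-to-hypo margin (`30/ISF` U) must drop glucose by 30 mg/dL at
   t = 150 min from equilibrium.  The drop is measured at 150 min — the
   middle of the 2–3 h window the limit formula is anchored to — rather
   than at the trajectory nadir, so that an overestimation of exactly
   `dCHO_max` lands the 2.5-h glucose at the hypoglycemia threshold, which
   is the premise of the limit.  A dose-proportional test dose is used
   instead of a fixed 1 U because pediatric sensitivities (ISF up to ~168
   mg/dL/U on this roster) exceed the 100 → 0 mg/dL headroom a 1 U bolus
   would need.
2. **`v_g` (distribution volume)** — the patient's largest scheduled meal,
   dosed exactly at `CHO/ICR`, must return glucose to target at
   t = 150 min.
3. **`tau_m` (meal absorption time constant)** — that same meal must peak
   0.5 mg/dL below the hyperglycemia threshold (`CONTROL_PEAK_MARGIN`).
   Stages 2–3 are solved jointly (nested bisection; the root is taken on
   the fast-absorption branch, where the peak decreases with `tau_m`).

Stage 3 encodes the study premise that the virtual subjects are
*well-controlled but ride the edge of the band*: without it, subjects with
small limits (children — per-gram glucose impact is `ISF/ICR =
30/dCHO_max`) overshoot 180 mg/dL under error-free dosing, while subjects
with large limits never approach the band edge and no error of any size
registers.  Anchoring the largest meal just inside the threshold makes the
control scenario clean (TIR = 100% for all 33 subjects, none excluded) and
makes limit-sized errors cross the band boundaries — the behavior the trial
exists to measure.  The anchor was chosen while designing the stand-in and
then frozen.

Consequences worth knowing: the realized ISF is exact at the 150-min mark
but dose-nonlinear away from it (the action term is multiplicative in G);
the calibrated `v_g` and `tau_m` absorb, rather than represent, anatomical
volumes and gastric emptying; and the basal rate that holds fasting
equilibrium is `60 * i_clear * i_basal` by construction, which
`steady_state_basal` recovers by bisection as a self-consistency check.

## Integration

Fixed-step RK4 on a 1-minute grid, meals and boluses applied as impulses at
event boundaries, glucose sampled every 5 minutes (288 samples/day).  The
vector field is smooth between events and its fastest time constant is
~10 min, so the local step error is orders of magnitude below what the
range-occupancy metrics can resolve; the kernel is numba-compiled, which
puts the full 33-patient × 10-experiment × 90-day study at roughly ten
seconds on one CPU.  Glucose cannot cross zero analytically (the sink terms
vanish as G → 0); non-finite or non-positive output still hard-errors as a
guard against degenerate parameter sets.

## Trial protocol

Five meals daily at 08:00 / 12:00 / 16:00 / 20:00 / 00:00 (the midnight
meal belongs to the same schedule day; the trial clock starts at the first
08:00 meal), cohort-specific gram plans, 90 days, 450 meals.  Every bolus
uses the simulated plasma glucose at the meal instant as preprandial G
(noise-free CGM), IOB = 0 throughout — the 4 h spacing leaves little
residual insulin, and modeling decay curves is out of scope.  Negative raw
boluses clamp to 0 U; carbohydrate estimates clamp to 0 g.  Doses are
continuous (no pen/pump quantization).  CGM noise is off by default so the
study is deterministic given the master seed.

Randomness is split from the master seed into one sub-stream per
(experiment, patient) via `SeedSequence(master_seed, spawn_key=(0,
experiment_index, sha256(patient_id)[:32 bits]))`, and one per
(experiment, metric, stratum) for the bootstrap, so any cell is
independently re-runnable and the full run reproduces byte-identically.

## Inference

Subjects with control-scenario TIR < 90% are excluded (none are, for this
calibrated roster); analyses run on two strata, always-in-range
(TIR = 100%) and TIR ≥ 90%.  For each experiment, metric and stratum the
per-subject paired differences vs the control are resampled with
replacement (10 000 resamples by default); the CI is the percentile
interval of the resampled mean and the two-sided p-value doubles the
smaller tail mass of the resampled mean around zero, clipped to [0, 1].  A
Shapiro–Wilk gate is available as a diagnostic, but the pipeline always
proceeds with the bootstrap — with ~30 subjects the percentile interval's
realized coverage is about 94% against a nominal 95% (verified by
simulation in the test suite), which is the known small-sample behavior of
the method.  No multiple-testing correction is applied; comparisons are
reported per experiment.  Degenerate resampling (all differences equal)
yields a point interval clamped to contain the observed mean.

## What the synthetic study does and does not show

The generator emulates the *design* of the original trial — the roster's
limit distribution, the meal plan, the error laws, the metrics and the
inference — on an open minimal model rather than the proprietary
FDA-accepted simulator.  Passing tests therefore demonstrate the internal
logic of the personalized limit (errors within the limit are benign, errors
at or beyond it degrade control in the direction the sign predicts, with
hyperglycemia from underestimation dominating), not the original study's
numeric effect sizes, which depend on unpublished patient parameters.  Not
modeled in the trial: CGM sensor error (plasma glucose is sampled directly;
an AR(1) sensor-noise overlay exists for sensitivity analyses but is off
everywhere), exercise, protein/fat effects, insulin stacking,
hypoglycemia counterregulation and rescue carbohydrates, and age-specific
meal-plan deviations.  Real-patient validation is explicitly out of scope.
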