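# Methods

This note documents the model, its assumptions, the calibration choices
made where the underlying study left quantities unpublished, and the
limits of what the synthetic data can show.

## Study setting

Two strategies for elective isolated CABG in patients with LVEF < 40%:
standard care (admission to the surgical ward 24 h pre-operatively;
n = 41 in the source cohort) versus preconditioning with a 24-h
levosimendan infusion started 48 h before surgery (coronary-unit
monitoring during the infusion, then 24 h on the ward; n = 13).
Four postoperative complications drive the economics: new-onset atrial
fibrillation (NOAF), low cardiac output (LCO; cardiogenic shock is its
severe extreme and implies LCO), renal failure (RF) and prolonged
(> 24 h) mechanical ventilation (MV). Effectiveness is the percentage of
patients free of all four; deaths are tracked as flags but are not a tree
state. The perspective is the public health service, the horizon runs
from intervention to discharge, and no discounting is applied.

## Cohort statistics

- Fourfold tables count events by arm; percentages are reported at one
  decimal (2/13 = 15.38% is displayed as 15.4%; the source tables print
  both 15.3 and 15.4 for the same count — we round half-up consistently).
- Pearson χ² uses the closed form N(ad−bc)²/(r₁r₂c₁c₂), optionally with
  the Yates adjustment; p from χ²₁.
- Fisher's exact test reports both sidednesses. The printed cardiogenic
  shock p-value (0.047) is the **one-sided** hypergeometric tail, so the
  one-sided convention is what reproduces the published number; the
  implementation labels sidedness explicitly rather than changing a
  default silently.
- The Mantel–Haenszel statistic across the two LVEF strata
  (35–40%, < 35%) uses the conditional hypergeometric moments with the
  n²(n−1) variance denominator and a continuity correction **on by
  default**: with the correction the strata {(0,5,20,13), (2,6,5,3)}
  give p = 0.0135 → 0.01 at 2 dp, matching the published table; without
  it p ≈ 0.005. (The source's running text says 0.02 where its table says
  0.01; we reproduce the table value and note the discrepancy rather than
  guess.) On a single stratum the statistic equals Pearson's χ² times
  (n−1)/n, and the implementation is cross-checked against statsmodels'
  `StratifiedTable`.
- Mann–Whitney U uses midranks, exact tails up to n = 20 per group and
  the continuity-corrected normal approximation above. No published
  continuous p-value is reproduced because per-patient continuous data
  are unpublished; these tests exist for synthetic-cohort summaries.
- No multiple-testing adjustment is applied (none was in the source).

## Decision tree

Topology: NOAF upstream of LCO; RF and MV conditionally independent given
LCO; all seven conditionals arm-specific. This is the minimal structure
consistent with the narrative ("LCO may or may not occur in relation to
prior atrial fibrillation and increases the incidence of renal failure
and prolonged ventilation"); every conditional is config-overridable.
Each arm therefore has 16 terminal pathways whose probabilities sum to 1
(enforced at 1e-9).

**Probabilities.** Only marginal complication counts and complication-free
totals were published, not the joint table. The packaged conditionals are
the empirical conditionals of the reconstructed 54-patient cohort (below):
intervention 2/13 NOAF, 2/11 LCO given no NOAF, etc. They reproduce every
published marginal exactly, but the *conditional* structure is a
calibration artifact of the reconstruction, and is labelled as such.

**Lengths of stay.** Additive: arm base days plus per-complication
increments (ICU: +1 NOAF, +3 LCO, +3 RF, +2 MV; ward: +1/+1/+2/+1),
shared between arms. Bases (ICU 1.50/2.48; ward 5.92/4.86 days) are
calibrated so the rolled-back means reproduce the observed strategy means
(ICU 2.50/5.70; ward 6.46/6.40 days). The increments themselves are
chosen on clinical grounds (LCO and RF dominate ICU prolongation) — the
study published strategy-level means only, so only the means are
identifiable.

**Costs.** The 23-item unit-cost catalogue is taken as printed (euros,
2 dp). Per-pathway resource quantities are **not** published; the packaged
profiles reconstruct routine care: one surgery, one ICU echocardiogram and
one pre-discharge ECG per patient; a daily ICU bundle (stay + laboratory
profile + ECG); a daily ward bundle (stay + usual oral medication);
complication add-ons (NOAF: amiodarone course; LCO: daily echo and amine
vials over a three-day episode; RF: two hemofilter kits + ten effluent
bags; MV: two extra ventilation days + three days of decontamination).
The intervention's pre-operative admission is costed as two levosimendan
vials (24 h at mid-range dosing), one coronary-unit day, one ward day and
monitoring work-up (two ECGs, two lab profiles, echo before and after the
infusion); the control arm's pre-operative day is one ward day plus the
routine work-up. The 460 € "mechanical ventilation at ICU" item is treated
as per-day (ambiguous in the price list) and charged only under prolonged
MV. Whether the preconditioning admission consumes one or two
coronary-unit days is equally ambiguous; the infusion lasts 24 h, so one
day is charged.

With these profiles the base case rolls back to €14,285.06 vs €16,746.68
(the published base case prints €14,792.33 vs €17,006.94 — within 3.5%
and 1.6% respectively). Because the quantities behind the published costs
are unrecoverable, cost agreement is treated as a *calibration property*
(5% bands) rather than an exact reproduction, and the tests enforce it
that way. Two further published inconsistencies are documented rather
than resolved: the printed difference row (2,274.61) does not equal the
printed column subtraction (17,006.94 − 14,792.33 = 2,214.61), so
`incremental()` always returns the arithmetic difference; and the
"base case" costs quoted in the deterministic-sensitivity text
(14,401/16,652) match the probabilistic row of the results table, so they
are treated as PSA means, not a second base case.

## Sensitivity analysis

**Deterministic.** The marginal LCO incidence of one arm is overridden to
published scenario values (intervention 18%/6%; control 35%/25%) by
rescaling both LCO conditionals by a common factor, preserving the
NOAF→LCO association. Expected cost is monotone increasing in the
override whenever every LCO-attributable cost and stay increment is
non-negative.

**Probabilistic.** 10,000 Monte Carlo draws; each draw re-evaluates the
full tree for both strategies.

- *Probabilities*: beta(occurrences, non-occurrences). Zero-event cells
  use the Jeffreys half-count adjustment (r+½, s+½), which nudges those
  distribution means slightly off the base case; the PSA means therefore
  converge to the model evaluated at the distribution means (the tree is
  multilinear in its independent parameters), which the tests assert
  explicitly. Raw 13-vs-41 counts would imply parameter uncertainty far
  wider than the published PSA intervals (e.g. ±13 percentage points on
  the intervention's complication-free share against a printed ±3), so
  the counts are scaled by an **evidence weight** (default 10), a
  calibration of the unpublished PSA parameterisation toward the
  published interval tightness. It is a config value, not a constant.
- *Unit costs*: gamma with the shape chosen so the central 95% interval
  spans mean·(1 ± 0.10) — the literal reading of "upper and lower limit
  of 10% around the mean" (CV ≈ 0.051). Cost draws are shared between
  strategies by default (toggleable), so shared prices cancel in the
  incremental.
- *Resource quantities and stays*: uniform on q·(1 ± 0.10), mirroring the
  10% convention; shared profiles share draws, arm-specific parameters
  (upfront profiles, base stays) draw per arm.
- One seeded generator; every parameter is drawn as a full vector in
  documented config order, so results are bit-reproducible per
  (config, seed).
- Summaries report means and 2.5/97.5 percentile intervals (the published
  "[95% CI]" does not state a method) and the dominance fraction: the
  share of draws where the intervention is cheaper *and* more effective.
  Under the packaged calibration every draw is dominant, matching the
  published claim that all simulations favoured preconditioning.

## Synthetic data

`generate_cohort` draws independent patients through the same conditional
chain (plus shock given LCO and death given shock) with log-normal stays
per (arm, complication-free) cell. Its defaults are the study conditions:
arm sizes 13/41, the reconstructed conditionals, LOS cells matched to the
published medians. It emulates the *event structure* the model assumes; it
does not emulate correlated comorbidities, time-varying hazards,
biomarkers, or any violation of the tree's conditional-independence
assumptions — so passing recovery tests shows the pipeline is internally
consistent, not that the tree is the true data-generating process of real
patients.

`study_cohort` is a deterministic 54-record reconstruction satisfying
every published margin: arm sizes; NOAF 2/9, LCO 2/25, shock 0/10 (nested
in LCO), RF 1/10, MV 1/9, deaths 0/5 (nested in shock); LVEF-stratified
LCO (0/5, 20/33) and (2/8, 5/8) with both intervention LCO cases in the
< 35% stratum; complication-free 7/13 and 13/41; and integer stays whose
medians/IQRs reproduce the published 2 (1–4) vs 4 (3–6) ICU and 6 (4–8)
vs 5 (4–9) ward days under SPSS-style (n+1)-position percentiles, with
sums tuned to the published means (exact integer sums force 2.54 vs the
printed 2.50 mean ICU stay in the intervention arm). In the intervention
arm the six complication events necessarily fall on six distinct patients
(7 complication-free out of 13 forces disjointness); in the control arm
the overlap pattern (7 of 9 NOAF within LCO, 9/10 RF and 8/9 MV within
LCO, one RF+MV patient without LCO) is **one** solution of the constraint
system — others exist, and nothing downstream treats it as published
per-patient data. `validate_study_cohort` re-checks every constraint and
is wired into the acceptance surface.

## Numerical conventions

- Probability conservation at 1e-9; roll-back equals exhaustive
  enumeration at 1e-9 (property-tested over 1,000 random parameter sets).
- Costs are floats internally; display rounding to 2 dp happens at the
  reporting edge only. Catalogue round-trips preserve values exactly.
- Percentile estimates use linear interpolation (numpy default) in the
  PSA and the (n+1)-position convention only where matching the published
  cohort quartiles.
- Degenerate inputs fail loudly: empty arms, zero marginals, probability
  leaks and unknown catalogue codes raise typed exceptions.

## Problem sizes

The default test-and-reproduction workload uses the 54-patient
reconstructed cohort, 10,000 PSA draws and 10,000-patient-per-arm recovery
cohorts; each stage completes in seconds on a single core.

## Known limitations

- The joint complication structure, per-pathway resource quantities and
  PSA parameter spreads are reconstructions calibrated to published
  aggregates; only the published aggregates themselves are evidence.
- The tree has no mortality state, no time dependence and no
  quality-of-life weighting; effectiveness is a binary complication-free
  indicator.
- Costs are local hospital-accounting prices in euros; transferability to
  other settings is limited, as the source itself cautions.
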