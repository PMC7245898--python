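# levocea

Cost-effectiveness analysis of **levosimendan preconditioning** before
elective coronary artery bypass graft (CABG) surgery in patients with
moderate-severe systolic dysfunction (LVEF < 40%).

Patients with a reduced ejection fraction who undergo CABG are at high risk
of postoperative **low cardiac output (LCO)**, which drags renal failure and
prolonged mechanical ventilation behind it and multiplies ICU days. Starting
a 24-hour levosimendan infusion 48 hours before surgery is a candidate
preventive strategy. This package implements the full economic evaluation of
that strategy for health-economics and ICU quality-improvement analysts:

1. **Cohort statistics** (`levocea.cohort`, `levocea.stats`) — per-patient
   records, event-by-arm fourfold tables, Pearson χ², Fisher's exact test
   (one- and two-sided), the Mantel–Haenszel stratified test across LVEF
   strata, and Student's t / Mann–Whitney U for continuous summaries.
2. **Costing** (`levocea.costing`) — a 23-item euro unit-cost catalogue
   (hospital accounting prices) and linear resource-profile costing.
3. **Decision model** (`levocea.model`, `levocea.config`) — a two-strategy
   decision tree with chance nodes NOAF → LCO → {renal failure ⊥ prolonged
   MV | LCO}, 16 terminal pathways per arm, additive length-of-stay model,
   and roll-back to expected cost, ICU/ward days and % complication-free
   patients, plus the incremental (dominance / ICER) result.
4. **Sensitivity analysis** (`levocea.sensitivity`) — univariate
   deterministic scenarios on the LCO incidence, and a Monte Carlo
   probabilistic sensitivity analysis (beta distributions on probabilities,
   gamma on unit costs, uniform on resource quantities) with
   cost-effectiveness-plane output, percentile intervals and dominance
   fractions.
5. **Synthetic data** (`levocea.synthetic`) — a seeded per-patient cohort
   generator under the same conditional event chain, and a deterministic
   54-patient reconstructed study cohort that satisfies every published
   marginal count.

## The model in brief

For each strategy *s* the tree assigns every pathway
ω ∈ {0,1}⁴ (indicators for NOAF, LCO, renal failure, prolonged MV) a
probability by the chain rule

P(ω) = P(NOAF) · P(LCO | NOAF) · P(RF | LCO) · P(MV | LCO),

a stay (base days of the arm plus additive per-complication increments) and
a cost (surgery + pre-operative admission + per-day ICU/ward bundles +
complication add-ons). Rolling back gives
E[cost], E[ICU days], E[ward days] and the effectiveness endpoint
*% patients free of all four complications*. The intervention **dominates**
when it is both cheaper and more effective; otherwise the incremental
cost-effectiveness ratio (euros per additional complication-free patient)
is reported. The PSA re-evaluates the whole tree for each of 10,000
parameter draws and plots incremental (effect, cost) pairs on the CE plane.

## Worked example

```python
import levocea as lv
from levocea.cohort import Arm

records = list(lv.study_cohort().records)          # 54 reconstructed patients
t = lv.tabulate(records, "lco")                    # (2, 11, 25, 16)
print(lv.arm_percentages(t))                       # (15.4, 61.0)
print(round(lv.pearson_chi2(t).p_value, 3))        # 0.004

config = lv.default_config()                       # calibrated base case
bc = lv.base_case(config)
e = bc.expectations[Arm.INTERVENTION]
print(round(e.expected_cost, 2), round(e.mean_icu_days, 2))   # 14285.06 2.5
e = bc.expectations[Arm.CONTROL]
print(round(e.expected_cost, 2), round(e.mean_icu_days, 2))   # 16746.68 5.7
print(bc.difference.dominance)                     # True

draws = lv.run_psa(config, lv.PSAConfig(n_draws=10_000, seed=1))
print(round(lv.ce_plane(draws).dominant.mean(), 3))            # 1.0
```

Reading: preconditioning costs about €14,285 per patient against €16,747
for standard care (a saving of ~€2,462), cuts the mean ICU stay from 5.7 to
2.5 days, raises the complication-free share from 30% to 57%, and stays
cheaper-and-more-effective in every Monte Carlo draw.

The same workflow is available from the shell:

```bash
levocea cohort --out cohort.csv --validate
levocea stats --cohort cohort.csv --stratify
levocea base-case
levocea dsa
levocea psa --draws 10000 --seed 1 --out plane.csv --summary psa.json
levocea run-all --seed 1 --out-dir results/
```

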