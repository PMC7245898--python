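# Deterministic sensitivity scenarios: published LCO incidences under
# alternative definitions, applied as overrides of the marginal LCO
# probability of one arm (conditionals rescaled proportionally).
- label: "LCO 18% (intervention)"
  arm: intervention
  p_lco: 0.18
  source_note: "upper published LCO incidence under levosimendan in CABG trials"
- label: "LCO 6% (intervention)"
  arm: intervention
  p_lco: 0.06
  source_note: "lower published LCO incidence under a restrictive definition"
- label: "LCO 35% (control)"
  arm: control
  p_lco: 0.35
  source_note: "upper published LCO incidence without preconditioning"
- label: "LCO 25% (control)"
  arm: control
  p_lco: 0.25
  source_note: "lower published LCO incidence without preconditioning"
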