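# Default unit-cost catalogue (euros, hospital-accounting prices).
# Each entry: label, unit_cost (EUR), category in
# {procedure, test, medication, stay}.
#
# Stay items and "mechanical_ventilation_day" are per day; medications are
# per unit dispensed (tablet, ampoule, vial, bag or day of paste/solution);
# "levosimendan" is one 12.5 mg vial.
surgery:
  label: "CABG surgery"
  unit_cost: 6269.20
  category: procedure
hemofilter_kit:
  label: "Hemofilter kit"
  unit_cost: 173.82
  category: procedure
mechanical_ventilation_day:
  label: "Mechanical ventilation at ICU (per day)"
  unit_cost: 460.00
  category: procedure
laboratory_profile:
  label: "Laboratory profile (haemogram, biochemistry, coagulation)"
  unit_cost: 85.96
  category: test
electrocardiogram:
  label: "Electrocardiogram"
  unit_cost: 20.37
  category: test
echocardiogram:
  label: "Echocardiogram"
  unit_cost: 120.36
  category: test
amiodarone_tablet:
  label: "Amiodarone prophylaxis (tablet)"
  unit_cost: 0.11
  category: medication
amiodarone_iv:
  label: "Amiodarone 150 mg (IV ampoule)"
  unit_cost: 0.25
  category: medication
furosemide_iv:
  label: "Furosemide 20 mg (IV ampoule)"
  unit_cost: 0.13
  category: medication
atorvastatin:
  label: "Atorvastatin 20 mg (tablet)"
  unit_cost: 0.07
  category: medication
bisoprolol:
  label: "Bisoprolol 5 mg (tablet)"
  unit_cost: 0.08
  category: medication
aspirin:
  label: "Acetylsalicylic acid 100 mg (tablet)"
  unit_cost: 0.03
  category: medication
dalteparin:
  label: "Dalteparin 5000 IU (SC, prefilled syringe)"
  unit_cost: 0.31
  category: medication
acetaminophen_iv:
  label: "Acetaminophen 1 g IV (vial)"
  unit_cost: 0.53
  category: medication
norepinephrine_vial:
  label: "Norepinephrine 10 mg (vial)"
  unit_cost: 0.95
  category: medication
dobutamine_vial:
  label: "Dobutamine 250 mg (vial)"
  unit_cost: 1.38
  category: medication
levosimendan:
  label: "Levosimendan 12.5 mg (vial)"
  unit_cost: 581.63
  category: medication
oral_paste_day:
  label: "Oral decontamination paste (per day)"
  unit_cost: 5.50
  category: medication
decontaminating_solution:
  label: "Decontaminating solution (per day)"
  unit_cost: 10.00
  category: medication
effluent_bag:
  label: "Effluent bag"
  unit_cost: 8.98
  category: medication
coronary_unit_day:
  label: "Coronary care unit (per day)"
  unit_cost: 909.79
  category: stay
icu_day:
  label: "ICU (per day)"
  unit_cost: 1266.95
  category: stay
ward_day:
  label: "Hospital ward (per day)"
  unit_cost: 234.12
  category: stay
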