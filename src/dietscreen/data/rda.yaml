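# Recommended dietary allowances used for the 0-10 nutrient scores
# (Dutch Health Council adult recommendations; iron is sex-specific,
# protein is expressed per kg body weight).
rda:
  vitamin_b6: {value: 1.5, units: mg/day}
  folate_eq: {value: 300, units: ug/day}
  vitamin_b12: {value: 2.8, units: ug/day}
  vitamin_d: {value: 10, units: ug/day}
  iron: {male: 9, female: 16, units: mg/day}
  protein: {value: 0.8, units: g/kg/day, per_kg: true}
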