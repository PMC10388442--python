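# The 16 scored components of the diet-quality index, with Dutch 2015
# dietary-guideline cut-offs. Each component scores 0-10; the total is 0-160.
# Units: g/day unless noted; alcohol in g ethanol/day; salt in g salt/day;
# unhealthy foods in servings/day.
components:
  - {name: vegetables, kind: adequacy, threshold: 200, units: g/day}
  - {name: fruits, kind: adequacy, threshold: 200, units: g/day}
  - {name: wholegrain products, kind: adequacy, threshold: 90, units: g/day}
  - {name: legumes, kind: adequacy, threshold: 10, units: g/day}
  - {name: nuts, kind: adequacy, threshold: 15, units: g/day}
  - {name: dairy, kind: optimum, zero_low: 0, opt_low: 300, opt_high: 450, zero_high: 750, units: g/day}
  - {name: fish, kind: adequacy, threshold: 15, units: g/day}
  - {name: tea, kind: adequacy, threshold: 450, units: g/day}
  - {name: fats and oils, kind: ratio, target: 1.0, units: soft share of added fats}
  - {name: coffee, kind: binary, direction: le, threshold: 0, units: g/day unfiltered coffee}
  - {name: red meat, kind: moderation, lower: 45, upper: 100, units: g/day}
  - {name: processed meat, kind: moderation, lower: 0, upper: 50, units: g/day}
  - {name: sweetened beverages and fruit juices, kind: moderation, lower: 0, upper: 250, units: g/day}
  - {name: alcohol, kind: moderation, lower: 10, upper: 30, units: g ethanol/day}
  - {name: salt, kind: moderation, lower: 6, upper: 12, units: g/day}
  - {name: unhealthy foods, kind: moderation, lower: 0, upper: 3, units: servings/day}
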