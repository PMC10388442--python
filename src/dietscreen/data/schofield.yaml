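# Schofield weight-only BMR equations: BMR (MJ/day) = slope * weight_kg + intercept.
# Bands match as age_min <= age < age_max.
bands:
  - {sex: male, age_min: 10, age_max: 18, slope_mj_per_kg: 0.074, intercept_mj: 2.754}
  - {sex: male, age_min: 18, age_max: 30, slope_mj_per_kg: 0.063, intercept_mj: 2.896}
  - {sex: male, age_min: 30, age_max: 60, slope_mj_per_kg: 0.048, intercept_mj: 3.653}
  - {sex: male, age_min: 60, age_max: 120, slope_mj_per_kg: 0.049, intercept_mj: 2.459}
  - {sex: female, age_min: 10, age_max: 18, slope_mj_per_kg: 0.056, intercept_mj: 2.898}
  - {sex: female, age_min: 18, age_max: 30, slope_mj_per_kg: 0.062, intercept_mj: 2.036}
  - {sex: female, age_min: 30, age_max: 60, slope_mj_per_kg: 0.034, intercept_mj: 3.538}
  - {sex: female, age_min: 60, age_max: 120, slope_mj_per_kg: 0.038, intercept_mj: 2.755}
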