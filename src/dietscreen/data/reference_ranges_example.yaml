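# EXAMPLE blood reference ranges mirroring typical Dutch hospital values.
# These are illustrative configuration data, not clinical truth: deployments
# must supply the ranges of their own laboratory.
analytes:
  vitamin_b6:
    units: nmol/L
    all: {low: 25, high: 100}
  folate:
    units: nmol/L
    all: {low: 7, high: 40}
  vitamin_b12:
    units: pmol/L
    all: {low: 145, high: 570}
  vitamin_d_25oh:
    units: nmol/L
    all: {low: 50, high: 250}
  haemoglobin:
    units: mmol/L
    male: {low: 8.5, high: 11.0}
    female: {low: 7.5, high: 10.0}
  ferritin:
    units: ug/L
    male: {low: 30, high: 400}
    female: {low: 15, high: 150}
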