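# Example configuration for `lipoptics predict-postprandial --config ...`
# Scenario entries are [label, fasting TG (mg/dL), postprandial delta-TG (mg/dL)].
scenarios:
  - [healthy, 50, 50]
  - [type2_diabetes, 200, 200]
  - [hypertriglyceridemia, 200, 1000]

# Hematocrit entering the Twersky dependent-scattering factor.
hematocrit: 0.33

# Per-wavelength packing factors (defaults shown; fitted from
# intralipid-in-bovine-blood titration at hematocrit 0.33).
packing_factors:
  730: 0.97
  880: 1.78
  1100: 1.61
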