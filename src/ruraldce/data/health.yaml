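# Health-effect parameters.  The density-outcome elasticities come from an
# external cross-national regression that is not reproduced here; the values
# below are PLACEHOLDER defaults of plausible sign and magnitude and must be
# reviewed before any applied use.  Baseline incidence figures are package
# defaults consistent with national mortality levels of the study period.
qaly_discount: 0.03
default_qaly_weight: 1.0
rural_incidence_share: null   # null: split incidence by population share
outcomes:
  - name: IMR
    elasticity: -0.24         # placeholder
    annual_incidence: 8500    # infant deaths per year
    event_age: 0
    life_expectancy_at_event: 67
  - name: U5MR
    elasticity: -0.26         # placeholder
    annual_incidence: 3400    # under-5 (non-infant) deaths per year
    event_age: 2.5
    life_expectancy_at_event: 65
  - name: MMR
    elasticity: -0.39         # placeholder
    annual_incidence: 800     # maternal deaths per year; mothers assumed age 25
    event_age: 25
    life_expectancy_at_event: 45
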