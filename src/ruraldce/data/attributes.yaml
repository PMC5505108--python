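# Job-posting attribute space of the Lao PDR medical-student choice survey:
# six attributes with 4/3/3/3/3/2 levels.  Salary carries numeric values
# (proportional pay increase) so it codes to a single continuous column whose
# coefficient is "per 100% of annual salary"; all other attributes are dummy
# coded against the stated reference level.
attributes:
  - name: salary
    levels: ["none", "30pct", "40pct", "50pct"]
    reference: "none"
    values: [0.0, 0.3, 0.4, 0.5]
  - name: housing
    levels: ["none", "allowance", "provision"]
    reference: "none"
  - name: transport
    levels: ["none", "official", "official_personal"]
    reference: "none"
  - name: promotion
    levels: ["two_year_wait", "one_year_wait", "immediate"]
    reference: "two_year_wait"
  - name: education
    levels: ["three_year_wait", "two_year_wait", "one_year_wait"]
    reference: "three_year_wait"
  - name: facility
    levels: ["baseline", "improved"]
    reference: "baseline"
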