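# Published mixed-logit coefficient table (mean utility, SE, mixing SD) for
# the medical-student sample, plus the salary basis.  Used both as the
# synthetic-data generating process and as the printed-parameter input to the
# valuation / preference-impact / projection stages.
salary_annual_usd: 1128
salary_lak_monthly: 751450
exchange_rate_lak_per_usd: 7993
coefficients:
  salary:                        {mean: 2.46, se: 0.17, sd: 0.0}
  "housing:allowance":           {mean: 0.71, se: 0.07, sd: 0.24}
  "housing:provision":           {mean: 0.68, se: 0.06, sd: 0.23}
  "transport:official":          {mean: 0.66, se: 0.06, sd: 0.12}
  "transport:official_personal": {mean: 0.80, se: 0.07, sd: 0.36}
  "promotion:one_year_wait":     {mean: 0.46, se: 0.06, sd: 0.10}
  "promotion:immediate":         {mean: 0.67, se: 0.08, sd: 0.80}
  "education:two_year_wait":     {mean: 0.62, se: 0.06, sd: 0.13}
  "education:one_year_wait":     {mean: 1.09, se: 0.08, sd: 0.59}
  "facility:improved":           {mean: 0.41, se: 0.06, sd: 0.80}
# Published valuation column (USD/year, rounded to the dollar)
printed_valuations:
  "housing:allowance": 326
  "housing:provision": 312
  "promotion:immediate": 307
  "promotion:one_year_wait": 211
  "education:one_year_wait": 500
  "education:two_year_wait": 284
  "facility:improved": 188
  "transport:official": 303
  "transport:official_personal": 367
# Published valuation/cost column
printed_ratios:
  "housing:allowance": 0.91
  "housing:provision": 0.75
  "promotion:immediate": 0.20
  "promotion:one_year_wait": 0.15
  "education:one_year_wait": 0.53
  "education:two_year_wait": 0.32
  "facility:improved": 0.18
  "transport:official": 0.48
  "transport:official_personal": 0.59
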