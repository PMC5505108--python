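# Published per-package cost-effectiveness inputs: 5-year cash-accounting
# direct cost (USD 2012), net discounted QALYs gained, and the three
# published average-cost-per-QALY columns (cash 5-year, depreciation 5-year,
# cash 30-year).  Used as inputs when exercising the ranking logic without
# re-deriving absolute costs.
packages:
  1:  {cost_5yr_cash: 2836963,  qalys_5yr: 534, acer_5yr_cash: 5311,  acer_5yr_depr: 4051,  acer_30yr_cash: 5487}
  2:  {cost_5yr_cash: 2826972,  qalys_5yr: 528, acer_5yr_cash: 5356,  acer_5yr_depr: 4088,  acer_30yr_cash: 5525}
  3:  {cost_5yr_cash: 2347845,  qalys_5yr: 484, acer_5yr_cash: 4851,  acer_5yr_depr: 3523,  acer_30yr_cash: 5150}
  4:  {cost_5yr_cash: 669983,   qalys_5yr: 461, acer_5yr_cash: 1454,  acer_5yr_depr: 1454,  acer_30yr_cash: 2380}
  5:  {cost_5yr_cash: 23594809, qalys_5yr: 472, acer_5yr_cash: 50022, acer_5yr_depr: 10481, acer_30yr_cash: 9965}
  6:  {cost_5yr_cash: 1283630,  qalys_5yr: 441, acer_5yr_cash: 2909,  acer_5yr_depr: 1511,  acer_30yr_cash: 3083}
  7:  {cost_5yr_cash: 1604154,  qalys_5yr: 426, acer_5yr_cash: 3769,  acer_5yr_depr: 3769,  acer_30yr_cash: 4530}
  8:  {cost_5yr_cash: 1594078,  qalys_5yr: 406, acer_5yr_cash: 3927,  acer_5yr_depr: 3927,  acer_30yr_cash: 4676}
  9:  {cost_5yr_cash: 22543898, qalys_5yr: 404, acer_5yr_cash: 55762, acer_5yr_depr: 9629,  acer_30yr_cash: 8838}
  10: {cost_5yr_cash: 1252563,  qalys_5yr: 353, acer_5yr_cash: 3550,  acer_5yr_depr: 3550,  acer_30yr_cash: 5092}
  11: {cost_5yr_cash: 536504,   qalys_5yr: 336, acer_5yr_cash: 1598,  acer_5yr_depr: 1598,  acer_30yr_cash: 2416}
  12: {cost_5yr_cash: 1239995,  qalys_5yr: 326, acer_5yr_cash: 3803,  acer_5yr_depr: 3803,  acer_30yr_cash: 5385}
  13: {cost_5yr_cash: 1114205,  qalys_5yr: 337, acer_5yr_cash: 3310,  acer_5yr_depr: 3310,  acer_30yr_cash: 4135}
  14: {cost_5yr_cash: 1670451,  qalys_5yr: 331, acer_5yr_cash: 5054,  acer_5yr_depr: 3390,  acer_30yr_cash: 4957}
  15: {cost_5yr_cash: 1047792,  qalys_5yr: 286, acer_5yr_cash: 3662,  acer_5yr_depr: 3662,  acer_30yr_cash: 4159}
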