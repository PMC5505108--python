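# Willingness-to-pay threshold: 3 x GDP per capita as published ($3786;
# note 3 x the published $1281 GDP per capita would be $3843 - the printed
# threshold is stored as-is).
threshold_usd_per_qaly: 3786
gdp_per_capita_usd: 1281
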