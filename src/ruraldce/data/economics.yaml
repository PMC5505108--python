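# Financial discounting and inflation conventions.  The published inflation
# path covers the first years (6.7%, then 5.3%); after the 5-year window the
# financial discount rate serves as the inflation rate.  Years 3-5 are
# package defaults interpolating between the published year-2 rate and the
# long-run discount rate.
discount_rate: 0.03
inflation_path: [0.067, 0.053, 0.047, 0.042, 0.038]
method: cash                  # 'cash' | 'depreciation'
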