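# The 15 candidate incentive packages, as component coefficient names.
# The published package listing does not state the career-promotion level;
# the default mapping uses immediate promotion (overridable).
packages:
  1:  ["housing:provision", "transport:official_personal", "promotion:immediate", "education:one_year_wait"]
  2:  ["housing:provision", "transport:official", "promotion:immediate", "education:one_year_wait"]
  3:  ["housing:provision", "transport:official", "education:one_year_wait"]
  4:  ["housing:allowance", "transport:official_personal", "promotion:immediate"]
  5:  ["transport:official_personal", "education:one_year_wait", "facility:improved"]
  6:  ["housing:provision", "transport:official", "promotion:immediate"]
  7:  ["transport:official_personal", "education:one_year_wait"]
  8:  ["transport:official", "education:one_year_wait"]
  9:  ["transport:official", "promotion:immediate", "facility:improved"]
  10: ["transport:official_personal", "education:two_year_wait"]
  11: ["transport:official", "promotion:immediate"]
  12: ["transport:official", "education:two_year_wait"]
  13: ["housing:allowance", "education:two_year_wait"]
  14: ["housing:provision", "education:two_year_wait"]
  15: ["education:one_year_wait"]
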