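# Public-system physician stocks (2011) and flow parameters.
public_mds: 1187
rural_public_mds: 273
public_share: 0.70            # public share of all physicians
sector_shares:                # 2011 entrant/stock shares by stratum
  private: 0.30
  public_urban: 0.54
  public_rural: 0.16
graduates_per_year: 180
attrition: 0.025
start_year: 2011
demography:
  base_year: 2011
  total_population: 6275000
  rural_population: 4131000
  growth_rate: 0.014          # annual total population growth
  urbanization_rate: 0.005    # annual relative decline of the rural share
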