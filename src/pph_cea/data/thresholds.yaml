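# Willingness-to-pay threshold configuration (USD per DALY averted).
# GDP per capita: approximate public 2022 values, current USD.
# Opportunity-cost shares: 51% of GDP per capita for Kenya, Nigeria and
# Tanzania; 71% for South Africa.
# Weights: hospital counts per country in the analysis sample (normalized
# internally); used for the pooled "weighted" thresholds.
gdp_per_capita_usd:
  kenya: 2099.0
  nigeria: 2163.0
  south_africa: 6766.0
  tanzania: 1192.0
opportunity_cost_share:
  kenya: 0.51
  nigeria: 0.51
  south_africa: 0.71
  tanzania: 0.51
weights:
  kenya: 14
  nigeria: 38
  south_africa: 14
  tanzania: 12
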