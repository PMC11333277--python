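currency,year,units_per_usd
USD,2019,1.0
USD,2020,1.0
USD,2021,1.0
USD,2022,1.0
USD,2023,1.0
KES,2020,106.5
KES,2021,109.6
KES,2022,117.9
NGN,2021,401.2
NGN,2022,423.0
ZAR,2021,14.8
ZAR,2022,16.4
TZS,2021,2298.0
TZS,2022,2303.0
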