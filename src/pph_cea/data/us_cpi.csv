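year,factor_to_2022
2019,1.139
2020,1.125
2021,1.080
2022,1.000
2023,0.96061
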