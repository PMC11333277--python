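country,index
kenya,1.00
nigeria,0.90
south_africa,2.20
tanzania,0.80
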