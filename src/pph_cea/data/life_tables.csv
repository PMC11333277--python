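country,age_years,remaining_le
kenya,15,53.8
kenya,20,49.1
kenya,25,44.5
kenya,30,40.0
kenya,35,35.5
kenya,40,31.1
kenya,45,26.8
kenya,50,22.6
nigeria,15,48.9
nigeria,20,44.5
nigeria,25,40.2
nigeria,30,36.0
nigeria,35,31.9
nigeria,40,27.9
nigeria,45,24.0
nigeria,50,20.3
south_africa,15,52.0
south_africa,20,47.3
south_africa,25,42.8
south_africa,30,38.5
south_africa,35,34.3
south_africa,40,30.2
south_africa,45,26.1
south_africa,50,22.1
tanzania,15,51.5
tanzania,20,46.9
tanzania,25,42.4
tanzania,30,38.0
tanzania,35,33.7
tanzania,40,29.5
tanzania,45,25.4
tanzania,50,21.5
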