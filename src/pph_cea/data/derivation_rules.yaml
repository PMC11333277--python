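# Costing rules for items not priced directly.
#   fraction_of: unit cost = factor x unit cost of another item (same country)
#   personnel_per_min: unit cost = per-minute rate of the lowest-grade doctor
#   zero: reprioritization of existing staff time, no additional resource
laparotomy:
  rule: fraction_of
  of: hysterectomy
  factor: 0.8
bimanual_compression_min:
  rule: personnel_per_min
physician_min:
  rule: personnel_per_min
uterine_massage:
  rule: zero
examination:
  rule: zero
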