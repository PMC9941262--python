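# Estimated total energy requirement of infants, including the energy
# deposition needed for growth, expressed per kg body weight.
# age_months: age band upper edge applies up to and including that age.
age_months,kj_per_kg_day
3,380
6,340
12,330
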