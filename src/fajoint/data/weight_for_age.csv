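# Default median body weight by age (sexes pooled), used when a measured
# weight is unavailable.
age_months,median_weight_kg
3,6.1
6,7.8
12,9.8
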