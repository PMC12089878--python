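ingredient_set,gi_spo2_low,gi_hr_low,gi_hr_high,gi_ibp_low,gi_ibp_high,sd_spo2_low,sd_hr_low,sd_hr_high,sd_ibp_low,sd_ibp_high
glucose_5|norepinephrine,0,0,0,1,0,0,0,0,0,1
fentanyl|midazolam,0,0,1,0,1,0,0,0,0,0
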