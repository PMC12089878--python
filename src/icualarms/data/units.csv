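unit,dimension,factor
mL/h,volume_per_time,1
ml/h,volume_per_time,1
mL/min,volume_per_time,60
L/h,volume_per_time,1000
mg/h,mass_per_time,1
mg/min,mass_per_time,60
ug/h,mass_per_time,0.001
ug/min,mass_per_time,0.06
g/h,mass_per_time,1000
mg/kg/h,mass_per_kg_time,1
ug/kg/min,mass_per_kg_time,0.06
mL,volume,1
L,volume,1000
mg,mass,1
ug,mass,0.001
g,mass,1000
mg/mL,mass_per_volume,1
ug/mL,mass_per_volume,0.001
g/L,mass_per_volume,1
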