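variable,phys_low,phys_high,life_low,life_high,outlier_low,outlier_high
fio2,0.21,0.8,0.21,1.0,0.0,1.0
peep,0,15,0,35,0,50
psupp,0,25,0,50,0,60
pinsp,5,30,0,60,0,80
set_rate,8,35,0,60,0,80
o2_flow_flowmeter,0,15,0,16,0,25
o2_flow_other,0,60,0,80,0,100
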