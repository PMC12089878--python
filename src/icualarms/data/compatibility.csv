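rst_level,o2_flow_flowmeter,o2_flow_other,fio2,peep,psupp,pinsp,set_rate
1,No,No,No,No,No,No,No
2,Yes,No,No,No,No,No,No
3,No,No,Yes,Yes,No,No,No
4,No,Yes,Yes,No,No,No,No
5,No,Yes,Yes,Yes,Yes,No,No
6,No,Yes,Yes,Yes,Yes,Yes,Yes
7,No,Yes,Yes,Yes,No,Yes,Yes
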