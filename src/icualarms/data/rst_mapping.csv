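vd_text,vm_text,ad_category,rst_category,rst_level
none,spontan,,spontaneous_breathing,1
Flowmeter,O2-Insufflation,,oxygen_therapy,2
O2-Brille,O2-Insufflation,,oxygen_therapy,2
O2-Maske,O2-Insufflation,,oxygen_therapy,2
CPAP-Geraet,CPAP,,cpap,3
Boussignac,CPAP,,cpap,3
Optiflow,High-Flow,,high_flow_oxygen_therapy,4
Airvo,High-Flow,,high_flow_oxygen_therapy,4
Evita,NIV-ASB,,noninvasive_ventilation,5
V60,NIV-PSV,,noninvasive_ventilation,5
Evita,CPAP/ASB,,augmented_ventilation,6
Evita,CPAP/ASB,niv_oronasal_mask,noninvasive_ventilation,5
Evita,CPAP/ASB,niv_full_face_mask,noninvasive_ventilation,5
Evita,CPAP/ASB,endotracheal_tube,augmented_ventilation,6
Evita,CPAP/ASB,tracheal_cannula,augmented_ventilation,6
Evita,BIPAP/ASB,,augmented_ventilation,6
Servo-i,PS,,augmented_ventilation,6
Evita,PCV,,controlled_ventilation,7
Evita,VCV,,controlled_ventilation,7
Servo-i,PRVC,,controlled_ventilation,7
Servo-i,VCV,,controlled_ventilation,7
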