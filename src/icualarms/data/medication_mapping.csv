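drug_id,active_ingredients,snomed_ct,route_category,technique,is_iv_fluid,gi_spo2_low,gi_hr_low,gi_hr_high,gi_ibp_low,gi_ibp_high,sd_spo2_low,sd_hr_low,sd_hr_high,sd_ibp_low,sd_ibp_high
D1001,norepinephrine,45555007,intravenous,continuous,0,0,0,0,1,0,0,0,0,0,1
D1002,epinephrine,387362001,intravenous,continuous,0,0,1,0,1,0,0,0,1,0,1
D1003,vasopressin,77671006,intravenous,continuous,0,0,0,0,1,0,0,0,0,0,1
D1010,propofol,387423006,intravenous,continuous,0,0,0,1,0,1,0,1,0,1,0
D1011,propofol,387423006,intravenous,continuous,0,0,0,1,0,1,0,1,0,1,0
D1020,nitroglycerin,387404004,intravenous,continuous,0,0,0,0,0,1,0,0,0,1,0
D1021,urapidil,395857004,intravenous,bolus,0,0,0,0,0,1,0,0,0,1,0
D1030,metoprolol,372826007,intravenous,bolus,0,0,0,1,0,0,0,1,0,0,0
D1031,amiodarone,372821002,intravenous,continuous,0,0,0,1,0,0,0,1,0,0,0
D1040,atropine,372862008,intravenous,bolus,0,0,1,0,0,0,0,0,0,0,0
D1050,salbutamol,372897005,inhalative,bolus,0,1,0,0,0,0,0,0,0,0,0
D1051,ipratropium,372518007,inhalative,bolus,0,1,0,0,0,0,0,0,0,0,0
D1052,theophylline,372810006,intravenous,continuous,0,1,0,0,0,0,0,0,0,0,0
D1060,furosemide,387475002,intravenous,bolus,0,1,0,0,0,1,0,0,0,1,0
D1070,nacl_0_9,346669006,intravenous,continuous,1,0,0,0,1,0,0,0,0,0,0
D1071,ringer_lactate,347280009,intravenous,continuous,1,0,0,0,1,0,0,0,0,0,0
D1080,enoxaparin,372562003,subcutaneous,bolus,0,0,0,0,0,0,0,0,0,0,0
D1081,paracetamol,387517004,enteral,bolus,0,0,0,0,0,0,0,0,0,0,0
D1082,fentanyl,373492002,transdermal,continuous,0,0,0,0,0,0,0,0,0,0,0
D1083,bupivacaine,387150008,epidural,continuous,0,0,0,0,0,0,0,0,0,0,0
D1084,midazolam,373476007,intramuscular,bolus,0,0,0,0,0,0,0,0,0,0,0
D1085,epinephrine,387362001,intraosseous,bolus,0,0,1,0,1,0,0,0,0,0,0
D2001,glucose_5|norepinephrine,,intravenous,continuous,0,0,0,0,1,0,0,0,0,0,1
D2002,fentanyl|midazolam,,intravenous,continuous,0,0,0,1,0,1,0,0,0,0,0
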