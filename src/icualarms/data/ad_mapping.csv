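raw_text,category,level,annotation_flag
kein AD,no_ad,1,1
no AD documented,no_ad,1,1
Wendl-Tubus,nasopharyngeal_airway,2,1
Guedel-Tubus,oropharyngeal_airway,2,1
Gesichtsmaske,face_mask,3,1
O2-Maske,face_mask,3,1
Venturi-Maske,venturi_mask,3,1
High-Flow Brille,high_flow_nasal_cannula,3,1
Maske,face_mask,3,0
Maske,niv_oronasal_mask,4,1
Maske,niv_full_face_mask,4,0
NIV-Maske,niv_oronasal_mask,4,1
Total-Face-Maske,niv_full_face_mask,4,1
CPAP-Helm,cpap_helmet,5,1
Helm,cpap_helmet,5,1
Helm,niv_helmet,5,0
NIV-Helm,niv_helmet,5,1
Larynxmaske,laryngeal_mask,6,1
LAMA,laryngeal_mask,6,1
Larynxtubus,laryngeal_tube,6,1
Kombitubus,combitube,7,1
supraglottisch sonstige,supraglottic_other,7,1
Koniotomie,cricothyrotomy_cannula,8,1
transtrachealer Katheter,transtracheal_catheter,8,1
Trachealkanuele,tracheal_cannula,9,1
TK,tracheal_cannula,9,1
Endotracheal tube,endotracheal_tube,9,1
Tubus,endotracheal_tube,9,1
ETT,endotracheal_tube,9,1
Optiflow Geraet,not_an_ad,0,1
Beatmungsgeraet,not_an_ad,0,1
Magensonde,not_an_ad,0,1
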