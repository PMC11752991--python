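variable,kind,level,good,poor
hypertension,count,no,96,19
hypertension,count,yes,111,77
preoperative_rupture,count,no,131,22
preoperative_rupture,count,yes,76,74
hunt_hess_high,count,no,145,33
hunt_hess_high,count,yes,62,63
fisher_high,count,no,194,70
fisher_high,count,yes,13,26
asa_high,count,no,131,44
asa_high,count,yes,76,52
multiple_aneurysms,count,no,166,65
multiple_aneurysms,count,yes,41,31
etomidate,count,no,171,89
etomidate,count,yes,36,7
intubation,count,no,18,47
intubation,count,yes,189,49
age,mean,,55.45,58.28
age,sd,,10.34,11.23
age,n,,207,96
surgical_time,mean,,156.34,40.23
surgical_time,sd,,21.99,7.28
surgical_time,n,,207,96
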