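variable,sex,lower,upper,style,units
wbc,male,4.0,9.2,closed_interval,10^9/L
wbc,female,3.7,9.2,closed_interval,10^9/L
neutrophil_pct,any,50,70,closed_interval,%
plt,any,100,300,closed_interval,10^9/L
rbc,male,4.1,5.7,closed_interval,10^12/L
rbc,female,3.7,5.1,closed_interval,10^12/L
hgb,male,131,172,closed_interval,g/L
hgb,female,113,151,closed_interval,g/L
hct,male,0.38,0.51,closed_interval,L/L
hct,female,0.34,0.45,closed_interval,L/L
mcv,male,83.9,99.1,closed_interval,fL
mcv,female,32.6,99.1,closed_interval,fL
mch,male,27.8,33.8,closed_interval,pg
mch,female,26.9,33.3,closed_interval,pg
mchc,male,320,355,closed_interval,g/L
mchc,female,322,362,closed_interval,g/L
blood_sugar,any,3.9,6.1,closed_interval,mmol/L
tc,any,,5.18,upper_only,mmol/L
tg,any,,1.70,upper_only,mmol/L
ldl_c,any,,3.37,upper_only,mmol/L
hdl_c,any,1.04,,lower_only,mmol/L
tbil,any,3.4,17.1,closed_interval,umol/L
dbil,any,,3.4,upper_only,umol/L
alt,any,,55,upper_only,U/L
alb,any,35,55,closed_interval,g/L
glob,any,9,34,closed_interval,g/L
bun,any,2.9,8.2,closed_interval,mmol/L
creatinine,any,53,140,closed_interval,umol/L
sua,any,240,490,closed_interval,umol/L
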