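# Published matrix-matched calibration lines (area = slope*conc + intercept,
# conc in ug/mL), determination coefficients, LOD/LOQ and linear ranges for
# the nine reference standards.
code,lod_ug_ml,loq_ug_ml,slope,intercept,r_squared,range_lo_ug_ml,range_hi_ug_ml
GI,1,2,632964,-95693,0.994,2,100
ER,1,2,14667,3462,0.996,2,100
CHB,1,2,718654,9443,0.994,2,100
TR,1,2,474132,-15725,0.996,2,100
MON,1,2,874152,84434,0.998,2,100
COF,1,2,364943,38924,0.997,2,100
COM,0.5,1,14793,2938,0.995,1,100
NA,0.5,1,261143,-18631,0.993,1,100
AP,1,2,914992,-115674,0.999,2,100
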