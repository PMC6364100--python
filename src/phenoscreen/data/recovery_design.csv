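# Published spike-recovery design: measured endogenous content (mg/kg dry
# sample; empty = not found) and mean recovery (%) / RSD (%) at the two
# fortification levels (n = 5 replicates each).
code,sample_mg_kg,recovery_50_pct,rsd_50_pct,recovery_200_pct,rsd_200_pct
GI,12.7,95.8,4.3,83.2,2.3
ER,345,93.8,4.4,97.5,7.2
CHB,300,82.1,6.8,97.2,3.8
TR,15,91.8,6.1,91.5,6.7
MON,,91.7,8.7,91.2,6.5
COF,250,93.6,6.3,89.4,6.2
COM,,95.4,6.2,92.7,6.3
NA,6.26,90.8,5.2,88.5,5.4
AP,125,88.6,3.6,94.2,4.7
DDB,16.7,92.5,4.2,91.5,4.3
MOL,220,88.7,5.3,93.8,5.4
CHT,32,97.2,3.9,91.7,5.8
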