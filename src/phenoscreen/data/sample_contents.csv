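# Published per-sample phenol contents (mg/kg dry sample) of four
# Dendrobium chrysotoxum samples; empty = below quantification / not found.
sample,GI,ER,CHB,TR,MON,COF,COM,NA,AP,DDB,MOL,CHT
1,12.7,345,300,15,,250,,6.26,8.5,16.7,220,32
2,8.9,520,324,,35,280,,8.93,5.9,18.6,187,21
3,,450,253,12.3,,267,,15.4,12.3,22.4,248,26
4,23.4,387,264,,24,189,,8.4,15.7,25.8,265,27
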