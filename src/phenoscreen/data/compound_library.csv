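# Twelve Dendrobium chrysotoxum phenols: nine reference standards plus three
# newly elucidated bibenzyls quantified against family surrogate standards.
# ions: semicolon list of mz<polarity>:relative_abundance (% of base peak).
# Notes: moscatilin [M+H]+ stored as 305 (= MW+1; one printed source gives 304,
# arithmetically inconsistent with MW 304). Coumarin's single ion is stored at
# 100 (a one-ion spectrum's only ion is its base peak). RTs of the three
# non-standards follow the self-consistent narrative assignment
# (MOL 5.62, CHT 6.84, DDB 6.97).
code,name,family,mw,rt_min,ions,has_negative_signal,sim_mz,sim_polarity,sim_start_min,sim_stop_min,surrogate,is_standard
GI,gigantol,bibenzyl,274,5.59,297+:100;275+:52,1,297,positive,3,8,GI,1
ER,erianin,bibenzyl,318,7.12,341+:100;319+:48,1,341,positive,6,9.5,ER,1
CHB,chrysotobibenzyl,bibenzyl,332,1.85,355+:100;333+:35,0,355,positive,0.5,3,CHB,1
TR,tristin,bibenzyl,260,2.90,283+:100;261+:46,1,283,positive,2,4,TR,1
MON,moscatin,phenanthrene,240,4.12,241+:100;213+:62,0,241,positive,3,7,MON,1
COF,confusarin,phenanthrene,300,5.41,301+:100;269+:48,0,301,positive,4,7,COF,1
COM,coumarin,coumarin,146,1.79,147+:100,0,147,positive,0.5,3,COM,1
NA,naringenin,flavone,272,4.39,271-:100,1,271,negative,3,6,NA,1
AP,apigenin,flavone,270,5.89,269-:100,1,269,negative,4.5,9,AP,1
DDB,"3,4-dihydroxy-5,4'-dimethoxybibenzyl",bibenzyl,274,6.97,297+:100;275+:50,1,297,positive,3,8,GI,0
MOL,moscatilin,bibenzyl,304,5.62,327+:100;305+:49,1,327,positive,4,8,ER,0
CHT,chrysotoxin,bibenzyl,318,6.84,319+:100;341+:83,1,341,positive,6,9.5,ER,0
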