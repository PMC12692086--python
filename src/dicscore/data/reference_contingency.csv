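score_id,subgroup,tp,fp,fn,tn
ORIGINAL,non_M3,13,58,4,54
ORIGINAL,M3,29,19,2,11
M3,non_M3,12,38,5,74
M3,M3,21,10,10,20
M7,non_M3,14,44,3,68
M7,M3,21,13,10,17
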