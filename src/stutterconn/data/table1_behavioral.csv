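participant_id,age,gender,site,ssi4,sample_id,task,total_syllables,repetitions,prolongations,blocks
AWS01,19,F,MGH,28,AWS01_combined,combined,791,11,0,54
AWS02,22,F,MGH,31,AWS02_combined,combined,542,18,11,84
AWS03,31,F,MGH,10,AWS03_combined,combined,704,3,0,9
AWS04,31,F,MGH,30,AWS04_combined,combined,737,6,4,45
AWS05,18,F,BU,14,AWS05_combined,combined,770,1,0,27
AWS06,23,M,MGH,20,AWS06_combined,combined,868,12,5,24
AWS07,19,M,MGH,9,AWS07_combined,combined,346,2,0,4
AWS08,29,M,MGH,33,AWS08_combined,combined,880,24,1,97
AWS09,58,M,MGH,14,AWS09_combined,combined,857,21,1,6
AWS10,42,M,MGH,22,AWS10_combined,combined,1069,21,1,13
AWS11,22,M,MGH,42,AWS11_combined,combined,248,4,3,24
AWS12,52,M,MGH,27,AWS12_combined,combined,698,10,0,29
AWS13,44,M,BU,20,AWS13_combined,combined,793,12,4,18
AWS14,29,M,BU,14,AWS14_combined,combined,847,16,9,15
AWS15,20,M,BU,18,AWS15_combined,combined,799,1,6,18
AWS16,43,M,BU,27,AWS16_combined,combined,913,49,17,15
AWS17,35,M,BU,30,AWS17_combined,combined,814,11,8,43
AWS18,22,M,BU,27,AWS18_combined,combined,759,10,1,28
AWS19,21,M,BU,19,AWS19_combined,combined,827,14,7,33
AWS20,20,M,BU,24,AWS20_combined,combined,812,1,1,33
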