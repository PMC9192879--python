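patient,age_years,followup_months,sex,angle_class,mandibular_advancement_mm,maxilla_advancement_mm,mandibular_setback_mm,maxilla_impaction_mm
1,27,12,M,III,,5,7,
2,37,14,M,III,,6,9,
3,20,15,F,III,,4,6,
4,22,13,M,III,,5,6,
5,25,15,F,III,,6,8,
6,32,12,F,III,,7,9,
7,21,12,M,III,,5,7,
8,25,13,F,II,8,,,4
9,23,13,M,III,,6,8,
10,32,13,M,III,,7,9,
11,19,12,M,III,,5,7,
12,22,12,M,II,9,,,5
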