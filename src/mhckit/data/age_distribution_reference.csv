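cohort,age_group,n_total,n_male,n_female
all,20 to 29,42,13,29
all,30 to 39,118,40,78
all,40 to 49,232,70,162
all,50 to 59,262,66,196
all,60 to 69,116,40,76
all,70 and more,24,9,15
2019,20 to 29,21,8,13
2019,30 to 39,73,27,46
2019,40 to 49,148,45,103
2019,50 to 59,170,44,126
2019,60 to 69,86,30,56
2019,70 and more,22,9,13
2020,20 to 29,21,5,16
2020,30 to 39,45,13,32
2020,40 to 49,84,25,59
2020,50 to 59,92,22,70
2020,60 to 69,30,10,20
2020,70 and more,2,0,2
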