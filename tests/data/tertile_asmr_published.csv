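city,sex,asmr_t1_p1,asmr_t3_p1,ratio_p1,diff_p1,asmr_t1_p2,asmr_t3_p2,ratio_p2,diff_p2,diff_t1,diff_t3,pct_reduction_t1,pct_reduction_t3
Aviles,men,1089,1299,1.19,210,1068,1152,1.08,84,21,147,2,11
Barcelona,men,1114,1438,1.29,324,945,1197,1.27,252,169,241,15,17
Bilbao,men,1296,1519,1.17,223,995,1186,1.19,191,301,333,23,22
Vigo,men,1093,1193,1.09,100,976,1108,1.14,132,117,85,11,7
Almeria,women,704,825,1.17,121,603,714,1.18,111,101,111,14,13
Aviles,women,656,687,1.05,31,490,589,1.20,99,166,98,25,14
Jaen,women,729,901,1.24,172,676,770,1.14,94,53,131,7,15
LasPalmas,women,773,821,1.06,48,587,727,1.24,140,186,94,24,11
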