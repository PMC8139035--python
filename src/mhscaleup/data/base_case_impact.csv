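disorder,2020,2021,2022,2023,2024,2025,2026,2027,2028,2029,2030,total
depression,0,35873,59717,78750,95490,110979,125688,139854,153611,167043,180231,1147236
anxiety,0,8235,13966,19595,25477,31699,38272,45177,52380,59847,67544,362192
bipolar,0,4461,6371,7658,8660,9498,10229,10884,11480,12027,12534,93802
epilepsy,0,1691,3423,5199,7018,8879,10774,12698,14645,16610,18588,99525
total,0,50260,83477,111202,136645,161055,184963,208613,232116,255527,278897,1702755
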