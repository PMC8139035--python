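component,2020,2021,2022,2023,2024,2025,2026,2027,2028,2029,2030,total
intervention,8448265,13488255,18621150,23847368,29150836,34514740,39924870,45361257,50808697,56257325,61698157,382120919
program,141575,301207,424001,560520,683314,819833,942627,1051697,1162739,1269838,1378908,8736258
labor,31012194,42009848,53232422,64666007,76263942,87984733,99796025,111651997,123519471,135378198,147209639,972724477
total,39602034,55799310,72277573,89073895,106098092,123319306,140663522,158064951,175490907,192905361,210286703,1363581654
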