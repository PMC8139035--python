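row,base_front_loaded,exponential,linear,epi_lower_CI,epi_upper_CI,coverage_1,coverage_2,coverage_3
intervention_costs_usd,382120919,390611079,387772875,305783940,476662810,392627220,448247779,372911819
program_costs_usd,8736258,8736258,8736258,8736258,8736258,8736258,8736258,8736258
labor_costs_usd,972724477,994357774,987228401,778324069,1213512516,1014058490,1065250321,934160222
total_costs_usd,1363581654,1393705112,1383737535,1092844267,1698911584,1415421968,1522234357,1315808299
depression_hly,1147236,753131,957688,934294,1403864,1105159,1439832,1105371
anxiety_hly,362192,282307,324450,316006,418867,310894,435672,311346
bipolar_hly,93802,38658,67133,65494,130647,93802,128165,93802
epilepsy_hly,99525,88300,94216,61126,150542,65234,99525,65716
total_hly,1702755,1162396,1443487,1376920,2103920,1575089,2103194,1576235
cost_per_hly_usd,801,1199,959,794,807,899,724,835
cost_per_hly_intl,7714,11548,9236,7647,7772,8658,6973,8042
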