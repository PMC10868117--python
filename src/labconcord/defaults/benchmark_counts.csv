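cohort,label_type,outcome,count,denominator
SickKids,abnormal,aki,4553,59298
SickKids,abnormal,hyperkalemia,5475,59298
SickKids,abnormal,hypoglycemia,3006,59298
SickKids,abnormal,hyponatremia,3888,59298
SickKids,abnormal,neutropenia,4263,59298
SickKids,abnormal,anemia,14839,59298
SickKids,abnormal,thrombocytopenia,10667,59298
StanfordPeds,abnormal,aki,2266,24639
StanfordPeds,abnormal,hyperkalemia,1596,24639
StanfordPeds,abnormal,hypoglycemia,1613,24639
StanfordPeds,abnormal,hyponatremia,4141,24639
StanfordPeds,abnormal,neutropenia,1804,24639
StanfordPeds,abnormal,anemia,10496,24639
StanfordPeds,abnormal,thrombocytopenia,3844,24639
StanfordAdults,abnormal,aki,41761,159985
StanfordAdults,abnormal,hyperkalemia,9790,159985
StanfordAdults,abnormal,hypoglycemia,12161,159985
StanfordAdults,abnormal,hyponatremia,53512,159985
StanfordAdults,abnormal,neutropenia,5085,159985
StanfordAdults,abnormal,anemia,119796,159985
StanfordAdults,abnormal,thrombocytopenia,44636,159985
SickKids,mild,aki,4478,59298
SickKids,mild,hyperkalemia,3408,59298
SickKids,mild,hypoglycemia,3844,59298
SickKids,mild,hyponatremia,6169,59298
SickKids,mild,neutropenia,4868,59298
SickKids,mild,anemia,21232,59298
SickKids,mild,thrombocytopenia,7061,59298
StanfordPeds,mild,aki,3461,24639
StanfordPeds,mild,hyperkalemia,1848,24639
StanfordPeds,mild,hypoglycemia,2197,24639
StanfordPeds,mild,hyponatremia,5648,24639
StanfordPeds,mild,neutropenia,1921,24639
StanfordPeds,mild,anemia,11436,24639
StanfordPeds,mild,thrombocytopenia,3844,24639
StanfordAdults,mild,aki,31930,159985
StanfordAdults,mild,hyperkalemia,9776,159985
StanfordAdults,mild,hypoglycemia,13115,159985
StanfordAdults,mild,hyponatremia,66559,159985
StanfordAdults,mild,neutropenia,5099,159985
StanfordAdults,mild,anemia,114488,159985
StanfordAdults,mild,thrombocytopenia,44636,159985
SickKids,moderate,aki,1650,59298
SickKids,moderate,hyperkalemia,1939,59298
SickKids,moderate,hypoglycemia,2084,59298
SickKids,moderate,hyponatremia,885,59298
SickKids,moderate,neutropenia,3346,59298
SickKids,moderate,anemia,17039,59298
SickKids,moderate,thrombocytopenia,4175,59298
StanfordPeds,moderate,aki,1550,24639
StanfordPeds,moderate,hyperkalemia,1137,24639
StanfordPeds,moderate,hypoglycemia,1178,24639
StanfordPeds,moderate,hyponatremia,917,24639
StanfordPeds,moderate,neutropenia,1172,24639
StanfordPeds,moderate,anemia,9429,24639
StanfordPeds,moderate,thrombocytopenia,2349,24639
StanfordAdults,moderate,aki,11321,159985
StanfordAdults,moderate,hyperkalemia,4790,159985
StanfordAdults,moderate,hypoglycemia,7366,159985
StanfordAdults,moderate,hyponatremia,15027,159985
StanfordAdults,moderate,neutropenia,2850,159985
StanfordAdults,moderate,anemia,91276,159985
StanfordAdults,moderate,thrombocytopenia,19327,159985
SickKids,severe,aki,616,59298
SickKids,severe,hyperkalemia,810,59298
SickKids,severe,hypoglycemia,1088,59298
SickKids,severe,hyponatremia,301,59298
SickKids,severe,neutropenia,2290,59298
SickKids,severe,anemia,2675,59298
SickKids,severe,thrombocytopenia,2328,59298
StanfordPeds,severe,aki,612,24639
StanfordPeds,severe,hyperkalemia,588,24639
StanfordPeds,severe,hypoglycemia,585,24639
StanfordPeds,severe,hyponatremia,269,24639
StanfordPeds,severe,neutropenia,635,24639
StanfordPeds,severe,anemia,1912,24639
StanfordPeds,severe,thrombocytopenia,1306,24639
StanfordAdults,severe,aki,5804,159985
StanfordAdults,severe,hyperkalemia,1331,159985
StanfordAdults,severe,hypoglycemia,4042,159985
StanfordAdults,severe,hyponatremia,3790,159985
StanfordAdults,severe,neutropenia,1316,159985
StanfordAdults,severe,anemia,14239,159985
StanfordAdults,severe,thrombocytopenia,7189,159985
SickKids,diagnosis,aki,176,59298
SickKids,diagnosis,hyperkalemia,38,59298
SickKids,diagnosis,hypoglycemia,209,59298
SickKids,diagnosis,hyponatremia,388,59298
SickKids,diagnosis,neutropenia,776,59298
SickKids,diagnosis,anemia,974,59298
SickKids,diagnosis,thrombocytopenia,192,59298
StanfordPeds,diagnosis,aki,1139,24639
StanfordPeds,diagnosis,hyperkalemia,353,24639
StanfordPeds,diagnosis,hypoglycemia,412,24639
StanfordPeds,diagnosis,hyponatremia,708,24639
StanfordPeds,diagnosis,neutropenia,790,24639
StanfordPeds,diagnosis,anemia,4238,24639
StanfordPeds,diagnosis,thrombocytopenia,2132,24639
StanfordAdults,diagnosis,aki,9440,159985
StanfordAdults,diagnosis,hyperkalemia,2453,159985
StanfordAdults,diagnosis,hypoglycemia,1385,159985
StanfordAdults,diagnosis,hyponatremia,5219,159985
StanfordAdults,diagnosis,neutropenia,1572,159985
StanfordAdults,diagnosis,anemia,30935,159985
StanfordAdults,diagnosis,thrombocytopenia,10334,159985
SickKids,mortality,in_hospital_mortality,297,59298
StanfordPeds,mortality,in_hospital_mortality,203,24639
StanfordAdults,mortality,in_hospital_mortality,3088,159985
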