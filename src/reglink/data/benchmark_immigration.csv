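section,stratum,n_linked,pct_linked,n_unlinked,pct_unlinked,std_diff,linkage_rate
Overall,Overall,2692178,,425156,,,86.4
Age at Landing,0-14,562971,20.9,94066,22.1,0.03,85.7
Age at Landing,15-24,444631,16.5,63434,14.9,0.04,87.5
Age at Landing,25-44,1246212,46.3,210673,49.6,0.07,85.5
Age at Landing,45-64,333864,12.4,43401,10.2,0.07,88.5
Age at Landing,65-84,101206,3.8,11486,2.7,0.06,89.8
Age at Landing,85+,3293,0.1,2073,0.5,0.07,61.4
Age at Landing,Missing,1,0,23,0,0.01,4.2
Sex,Female,1371981,51.0,229325,53.9,0.06,85.7
Sex,Male,1320197,49.0,195365,46.0,0.06,87.1
Sex,Missing,0,0,466,0.1,0.05,0
Year of Landing,1985-1989,279144,10.4,89577,21.1,0.30,75.7
Year of Landing,1990-1994,544215,20.2,81689,19.2,0.03,86.9
Year of Landing,1995-1999,475300,17.7,74667,17.6,0,86.4
Year of Landing,2000-2004,589321,21.9,71234,16.8,0.13,89.2
Year of Landing,2005-2012,804198,29.9,107989,25.4,0.10,88.2
Immigration Class,Family Class,946189,35.1,108446,25.5,0.21,89.7
Immigration Class,Economic Immigrants,1277970,47.5,270399,63.6,0.33,82.5
Immigration Class,Refugees/Asylum Seekers,405039,15.0,36974,8.7,0.20,91.6
Immigration Class,Other,42896,1.6,5455,1.3,0.03,88.7
Immigration Class,No categorization,20084,0.7,3882,0.9,0.02,83.8
Marital Status,Married/Common-Law,1364683,50.7,210753,49.6,0.02,86.6
Marital Status,Single,1209074,44.9,200247,47.1,0.04,85.8
Marital Status,Widowed/Divorced/Separated,117987,4.4,14075,3.3,0.06,89.3
Marital Status,Missing,434,0,81,0,0,84.3
Region of Birth,North America,66963,2.5,16521,3.9,0.08,80.2
Region of Birth,Central America,53667,2.0,6402,1.5,0.04,89.3
Region of Birth,Caribbean/Bermuda,154328,5.7,12360,2.9,0.14,92.6
Region of Birth,South America,132972,4.9,15087,3.5,0.07,89.8
Region of Birth,Western Europe,31213,1.2,6961,1.6,0.04,81.8
Region of Birth,North Europe,71056,2.6,13471,3.2,0.03,84.1
Region of Birth,Eastern Europe,241900,9.0,23958,5.6,0.13,91.0
Region of Birth,Southern Europe,116687,4.3,12948,3.0,0.07,90.0
Region of Birth,West Central Asia and the Middle East,293208,10.9,39958,9.4,0.05,88.0
Region of Birth,Eastern Asia,451486,16.8,127466,30.0,0.32,78.0
Region of Birth,South East Asia,254888,9.5,37163,8.7,0.03,87.3
Region of Birth,Southern Asia,612233,22.7,82627,19.4,0.08,88.1
Region of Birth,Oceania,8340,0.3,1467,0.3,0.01,85.0
Region of Birth,Western Africa,41188,1.5,4068,1.0,0.05,91.0
Region of Birth,Northern Africa,49382,1.8,11072,2.6,0.05,81.7
Region of Birth,Central Africa,10155,0.4,1310,0.3,0.01,88.6
Region of Birth,Eastern Africa,87149,3.2,9538,2.2,0.06,90.1
Region of Birth,Southern Africa,14559,0.5,2401,0.6,0,85.8
Region of Birth,Country not stated,804,0,378,0.1,0.02,68.0
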