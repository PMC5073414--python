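section,stratum,n_linked,pct_linked,n_unlinked,pct_unlinked,std_diff,linkage_rate
Overall,Overall,1833354,,73373,,,96.2
Age at Death,0-14,19483,1.1,6293,8.6,0.36,75.6
Age at Death,15-24,15204,0.8,1517,2.1,0.10,90.9
Age at Death,25-44,70023,3.8,5497,7.5,0.16,92.7
Age at Death,45-64,293856,16.0,14126,19.3,0.08,95.4
Age at Death,65-84,909667,49.6,32052,43.7,0.12,96.6
Age at Death,85+,525085,28.6,13787,18.8,0.23,97.4
Age at Death,Missing,36,0,101,0.1,0.05,26.3
Sex,Female,906234,49.4,31261,42.6,0.14,96.7
Sex,Male,927110,50.6,42077,57.3,0.14,95.7
Sex,Missing,10,0,35,0,0.03,22.2
Cause of Death,Infectious and Parasitic Diseases,32456,1.8,1222,1.7,0.01,96.4
Cause of Death,Neoplasms,536603,29.3,15780,21.5,0.18,97.1
Cause of Death,Endocrine Nutritional and Metabolic Diseases,74205,4.0,2352,3.2,0.05,96.9
Cause of Death,Diseases of the Blood,5940,0.3,248,0.3,0,96.0
Cause of Death,Mental Disorders,62774,3.4,1301,1.8,0.10,98.0
Cause of Death,Diseases of the Nervous System,70297,3.8,1676,2.3,0.09,97.7
Cause of Death,Diseases of the Sense Organs,100,0,6,0,0,94.3
Cause of Death,Diseases of the Circulatory System,621713,33.9,26744,36.4,0.05,95.9
Cause of Death,Diseases of the Respiratory System,153350,8.4,5466,7.4,0.03,96.6
Cause of Death,Diseases of the Digestive System,72477,4,2644,3.6,0.02,96.5
Cause of Death,Diseases of the Genitourinary System,35042,1.9,968,1.3,0.05,97.3
Cause of Death,Complications of Pregnancy and Childbirth,134,0,13,0,0.01,91.2
Cause of Death,Diseases of the Skin,3008,0.2,97,0.1,0.01,96.9
Cause of Death,Diseases of the Musculoskeletal System,10094,0.6,246,0.3,0.03,97.6
Cause of Death,Congenital Anomalies,7246,0.4,1671,2.3,0.16,81.3
Cause of Death,Perinatal Conditions,5846,0.3,3688,5.0,0.30,61.3
Cause of Death,Symptoms Signs and Ill-Defined Conditions,20624,1.1,1942,2.6,0.11,91.4
Cause of Death,External Causes of Injury and Poisoning,105662,5.8,7014,9.6,0.14,93.8
Cause of Death,Missing,15783,0.9,295,0.4,0.06,98.2
Fiscal Year of Death,1990-1994,346805,18.9,45885,62.5,0.99,88.3
Fiscal Year of Death,1995-1999,392282,21.4,9234,12.6,0.24,97.7
Fiscal Year of Death,2000-2004,406196,22.2,8406,11.5,0.29,98.0
Fiscal Year of Death,2005-2009,428974,23.4,6207,8.5,0.42,98.6
Fiscal Year of Death,2010-2012,259097,14.1,3616,4.9,0.32,98.6
Fiscal Year of Death,Missing,0,0,25,0,0.03,0
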