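no,name,name_printed,ci_obs,ci_calc,set,excluded
1,Abacavir,Abacavir,0.47,0.62,test,false
2,Acipimox,Acipimox,0.25,0.38,train,false
3,Acyclovir,Acyclovir,0.17,0.09,test,false
4,Alanine,Alanine,0.30,0.40,test,false
5,Alfentanil,Alfentanil,0.75,0.68,train,false
6,PAH,PAH,0.47,0.41,train,false
7,Amprenavir,Amprenavir,0.38,0.39,test,false
8,Azidothymidine,Azidothymidine,0.29,0.15,test,false
9,Betamethasone,Betamethasone,0.41,0.44,train,false
10,Biotin,Biotin,0.35,0.43,train,false
11,Bisheteroypiperazine,Bisheteroypiperazine,0.72,0.65,train,false
12,Buprenorphine,Buprenorphine,0.29,0.32,train,false
13,Cefoperazone,Cefoperazone,0.04,0.06,train,false
14,Cefpirome,Cefpirome,0.20,0.02,train,false
15,Ceftizoxime,Ceftizoxime,0.12,0.04,test,false
16,Chloroprocaine,Chloroprocaine,0.83,0.69,test,false
17,L-Leucine,L-Leucine,0.62,0.55,train,false
18,Lidocaine,Lidocaine,0.91,0.96,train,false
19,Bupivacaine,Bupivacaine,0.73,0.91,test,false
20,Cimetidine,Cimetidine,0.30,0.38,test,false
21,Clavulanic acid,Clavulanic acid,0.06,0.11,train,false
22,Cocaethylene,Cocaethylene,0.78,0.82,train,false
23,Cocaine,Cocaine,0.88,0.74,train,false
24,Cortisol,Cortisol,0.50,0.54,test,false
25,Cortisone,Cortisone,0.74,0.63,train,false
26,Creatinine,Creatinine,0.31,0.36,train,false
27,D4T,D4T,0.24,0.25,train,false
28,DDE,DDE,0.61,0.68,train,false
29,Dexamethasone,Dexamethasone,0.37,0.44,train,false
30,Dichlorobenzene,Dichlorobenzene,0.98,0.99,train,false
31,Diclofenac,Diclofenac,0.79,0.68,train,false
32,Didanosine,Didanosine,0.31,0.29,test,false
33,Ethanol,Ethanol,1.07,1.05,train,false
34,Fenoterol,Fenoterol,0.10,0.18,train,false
35,Ganciclovir,Ganciclovir,0.17,0.08,train,false
36,Glucose,Glucose,0.26,0.50,test,false
37,Hydralazine,Hydralazine,0.61,0.62,train,false
38,Indinavir,Indinavir,0.39,0.34,train,false
39,Indomethacin,Indomethacin,0.72,0.58,test,false
40,L-Alpha-acetyl-N-normethadol,L-Alpha-acetyl-N-normethadol,0.80,0.88,test,false
41,L-Alphacetylmethadol,L-Alphacetylmethadol,0.95,0.92,train,false
42,Lamivudine,Lamivudine,0.23,0.19,train,false
43,Lysine,Lysine,0.35,0.29,train,false
44,Lopinavir,Lopinavir,0.73,0.60,train,false
45,Mefloquine,Mefloquine,1.57,,train,true
46,Meropenem,Meropenem,0.08,0.16,train,false
47,Metaclopramide,Metaclopramide,0.40,0.65,train,false
48,Metformin,Metformin,0.34,0.44,train,false
49,Methadone,Methadone,0.83,0.97,train,false
50,Mezlocilline,Mezlocilline,0.14,-0.08,test,false
51,Morphine,Morphine,0.63,0.36,test,false
52,Naloxone,Naloxone,0.64,0.46,train,false
53,Nicotine,Nicotine,0.93,0.54,test,false
54,Oseltamivir,Oseltamivir,0.13,0.28,train,false
55,Hydroxyphenytoin,Hydroxyphenytoin,0.52,0.51,train,false
56,PCB-52,PCB-52,0.74,0.62,train,false
57,Pentamidine,Pentamidine,0.04,0.04,train,false
58,Phenobarbitone,Phenobarbitone,0.52,0.63,train,false
59,Prednisolone,Prednisolone,0.38,0.46,test,false
60,Propofol,Propofol,0.51,0.58,train,false
61,Pyridoxal,Pyridoxal,0.37,0.40,train,false
62,Pyridoxal 5'-phosphate,Pyridoxal 5'-phosphate,0.07,0.06,train,false
63,Pyridoxine,Pyridoxine,0.56,0.45,train,false
64,Pyrimethamine,Pyrimethamine,1.00,1.03,train,false
65,Quabain,Quabain,0.07,0.07,train,false
66,Riboflavin,Ribofl avin,0.69,0.74,train,false
67,Rifabutin,Rifabutin,0.37,0.42,train,false
68,Rifampin,Rifampin,0.12,0.76,test,false
69,Ritodrine,Ritodrine,0.10,0.04,train,false
70,Ritonavir,Ritonavir,0.09,0.07,train,false
71,Ropivacaine,Ropivacaine,0.75,0.94,test,false
72,Rosiglitazone,Rosiglitazone,0.20,0.35,train,false
73,Salbutamol,Salbutamol,0.40,0.30,train,false
74,Saquinavir,Saquinavir,0.05,0.09,train,false
75,S-Ketoprofen,S-Ketoprofen,0.39,0.91,test,false
76,SR49059,SR49059,0.31,0.33,train,false
77,Sufentanil,Sufentanil,0.66,0.65,train,false
78,Sulindac,Sulindac,0.47,0.60,train,false
79,Sulindac sulfide,Sulindac sulfide,0.81,0.64,train,false
80,Theophylline,Theophylline,0.80,0.64,train,false
81,Thiopental,Thiopental,0.95,0.89,train,false
82,Ticarcillin,Ticarcillin,0.04,0.14,train,false
83,Triameterene,Triameterene,0.85,0.80,test,false
84,Trovafloxacin,Trovafl oxacin,0.19,0.23,train,false
85,Urea,Urea,0.32,0.28,train,false
86,Valproic acid,Valproic acid,0.95,0.93,train,false
87,Vinblastine,Vinblastine,0.31,0.23,train,false
88,Zalcitabine,Zalcitabine,0.22,0.34,train,false
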