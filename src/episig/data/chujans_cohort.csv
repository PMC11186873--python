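study_number,gene,variant,protein,variant_type,variant_class,sex,role
1,PHIP,c.2744_2747del,p.(Lys915Serfs*15),FS,LP,F,training
2,PHIP,c.4431_4432del,p.(Phe1478Leufs*19),FS,LP,M,training
3,PHIP,c.3571C>T,p.(Gln1191*),NS,LP/P,M,training
4,PHIP,c.919_923del,p.(Ile307Profs*22),FS,LP/P,F,training
5,PHIP,c.4060A>T,p.(Arg1354*),NS,LP/P,F,training
6,PHIP,c.3447T>G,p.(Tyr1149*),NS,LP/P,F,training
7,PHIP,c.1900C>T,p.(Gln634*),NS,LP/P,F,training
8,PHIP,c.3278T>G,p.(Leu1093Arg),Mis,LP,M,training
9,PHIP,c.2306_2309del,p.(Pro769Leufs*43),FS,LP,F,training
10,PHIP,c.1186C>T,p.(Arg396*),NS,P,F,training
11,PHIP,c.613dup,p.(Cys205Leufs*10),FS,P,F,training
12,PHIP,c.3G>A,p.(?),SL,LP,M,training
13,PHIP,c.464T>C,p.(Leu155Pro),Mis,LP,F,training
14,PHIP,c.1558dup,p.(Cys520Leufs*6),FS,LP,M,validation
15,PHIP,c.1663_1667del,p.(Gln555Valfs*4),FS,P,M,validation
16,PHIP,c.328C>T,p.(Arg110Cys),Mis,LP,M,validation
17,PHIP,c.328C>T,p.(Arg110Cys),Mis,LP,F,validation
18,PHIP,c.3947dup,p.(Tyr1316*),NS,P,F,validation
19,PHIP,c.3922A>T,p.(Arg1308*),NS,P,M,validation
20,PHIP,c.2759_2762del,p.(Arg920Asnfs*10),FS,P,F,validation
21,PHIP,c.3922A>T,p.(Arg1308*),NS,P,F,validation
22,PHIP,c.3922A>T,p.(Arg1308*),NS,P,F,validation
23,PHIP,c.2200A>G,p.(Ser734Gly),Mis,VUS,M,validation
24,PHIP,c.686C>T,p.(Ser229Leu),Mis,LP,M,validation
25,PHIP,c.668G>T,p.(Gly223Val),Mis,LP,M,validation
26,PHIP,c.1095+5G>C,p.?,Splice,LP,M,validation
27,PHIP,c.52C>T,p.(Leu18Phe),Mis,LP,F,validation
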