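study_number,gene,transcript,variant,protein,variant_type,variant_class,sex,role
28,PHF6,NM_001015877.2,c.1024C>T,p.(Arg342*),NS,P,M,discovery
29,PHF6,NM_001015877.2,c.1022A>G,p.(Glu341Gly),Mis,LP,M,discovery
30,PHF6,NM_001015877.2,c.1021G>C,p.(Glu341Gln),Mis,LP,M,discovery
31,PHF6,NM_001015877.2,c.48dup,p.(Cys17Metfs*5),FS,LP,M,discovery
32,PHF6,NM_001015877.2,c.266G>A,p.(Gly89Glu),Mis,LP,M,discovery
33,PHF6,NM_001015877.2,c.769A>G,p.(Arg257Gly),Mis,P,M,discovery
34,PHF6,NM_001015877.2,c.1024C>T,p.(Arg342*),NS,P,M,discovery
35,PHF6,NM_001015877.2,c.134G>A,p.(Cys45Tyr),Mis,P,M,discovery
36,PHF6,NM_001015877.2,c.22A>T,p.(Lys8*),NS,P,M,discovery
37,PHF6,NM_001015877.2,c.2T>C,p.?,SL,P,M,discovery
38,PHF6,NM_001015877.2,c.134G>A,p.(Cys45Tyr),Mis,P,M,discovery
39,PHF6,NM_001015877.2,c.296G>T,p.(Cys99Phe),Mis,LP,M,discovery
40,PHF6,NM_001015877.2,c.1024C>T,p.(Arg342*),NS,P,M,discovery
41,PHF6,NM_001015877.2,c.1024C>T,p.(Arg342*),NS,P,M,discovery
42,PHF6,NM_001015877.2,c.860G>A,p.(Gly287Asp),Mis,LP,F,testing
43,PHF6,NM_001015877.2,c.715C>T,p.(His239Tyr),Mis,LP,F,testing
44,PHF6,NM_001015877.2,c.800C>T,p.(Thr267Ile),Mis,LP,F,testing
45,PHF6,NM_001015877.2,c.1039C>T,p.(Arg347*),NS,LP,M,testing
46,PHF6,NM_001015877.2,c.199A>G,p.(Ile67Val),Mis,VUS,M,testing
47,PHF6,NM_001015877.2,c.827A>G,p.(Lys276Arg),Mis,VUS,M,testing
48,PHF6,NM_001015877.2,c.434G>A,p.(Ser145Asn),Mis,VUS,M,testing
49,PHF6,NM_001015877.2,c.890G>T,p.(Cys297Phe),Mis,P,F,testing
50,PHF6,NM_001015877.2,c.266G>A,p.(Gly89Glu),Mis,LP,M,testing
51,PHF6,NM_001015877.2,c.122C>T,p.(Ala41Val),Mis,VUS,M,testing
52,DDB1,NM_001923.5,c.637G>A,p.(Glu213Lys),Mis,P,M,discovery
53,DDB1,NM_001923.5,c.637G>A,p.(Glu213Lys),Mis,P,F,discovery
54,DDB1,NM_001923.5,c.643G>A,p.(Glu215Lys),Mis,P,F,discovery
55,DDB1,NM_001923.5,c.562C>T,p.(Arg188Trp),Mis,VUS,F,discovery
56,DDB1,NM_001923.5,c.3169C>T,p.(Arg1057*),NS,VUS,M,testing
57,DDB1,NM_001923.5,c.2683A>G,p.(Thr895Ala),Mis,VUS,M,testing
58,DDB1,NM_001923.5,c.637G>A,p.(Glu213Lys),Mis,P,M,testing
59,DDB1,NM_001923.5,c.562C>T,p.(Arg188Trp),Mis,VUS,F,testing
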