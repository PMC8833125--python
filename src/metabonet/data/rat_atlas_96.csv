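region_id,name,abbreviation,hemisphere
1,"Nucleus Accumbens Core_R",AcbC_R,R
2,"Nucleus Accumbens Shell_R",AcbSh_R,R
3,"Amygdala_R",Amy_R,R
4,"Bed Nucleus of the Stria Terminalis_R",BNST_R,R
5,"Caudate Putamen_R",CPu_R,R
6,"Corpus Collosum_R",CoC_R,R
7,"Cortex- Auditory_R",Aud_R,R
8,"Cortex- Cingulate_R",CiC_R,R
9,"Cortex- Entorhinal_R",EC_R,R
10,"Cortex- Frontal Association_R",FrA_R,R
11,"Cortex- Insular_R",In_R,R
12,"Cortex-Medial Prefrontal_R",mPFC_R,R
13,"Cortex- Motor_R",M1_R,R
14,"Cortex- Orbitofrontal_R",OFC_R,R
15,"Cortex- Parietal Association_R",ParA_R,R
16,"Piriform Cortex_R",PC_R,R
17,"Cortex- Retrosplenial_R",RSC_R,R
18,"Cortex- Somatosensory_R",S1_R,R
19,"Cortex- Temporal Association_R",TeA_R,R
20,"Cortex- Visual_R",V1_R,R
21,"Diagonal Band_R",DB_R,R
22,"Globus Pallidus_R",GPa_R,R
23,"Antero-Dorsal Hippocampus_R",adHIP_R,R
24,"Posterior Hippocampus_R",pHIP_R,R
25,"Postero-Dorsal Hippocampus_R",pdHIP_R,R
26,"Hippocampus Subiculum_R",sHIP_R,R
27,"Ventral Hippocampus_R",vHPC_R,R
28,"Lateral Hypothalamus_R",LH_R,R
29,"Medial Hypothalamus_R",MH_R,R
30,"Internal Capsule_R",Ic_R,R
31,"Interstitial Nucleus of the Posterior Limb of the Anterior Commissure_R",IPAC_R,R
32,"Medial Geniculate_R",MG_R,R
33,"Mesencephalic Region_R",MR_R,R
34,"Olfactory Nuclei_R",ON_R,R
35,"Olfactory Tubercle_R",OT_R,R
36,"Periaqueductal Grey_R",PAG_R,R
37,"Pons_R",Pons_R,R
38,"Raphe_R",Raphe_R,R
39,"Septum_R",Septum_R,R
40,"Substantia Innominata_R",SI_R,R
41,"Substantia Nigra_R",SN_R,R
42,"Superior Colliculus_R",SC_R,R
43,"Dorsolateral Thalamus_R",DLT_R,R
44,"Dorsal Midline Thalamus_R",dMT_R,R
45,"Ventromedial Thalamus_R",VMT_R,R
46,"Ventral Pallidum_R",VP_R,R
47,"Ventral Tegmental Area_R",VTA_R,R
48,"Zona Incerta_R",ZI_R,R
49,"Nucleus Accumbens Core_L",AcbC_L,L
50,"Nucleus Accumbens Shell_L",AcbSh_L,L
51,"Amygdala_L",Amy_L,L
52,"Bed Nucleus of the Stria Terminalis_L",BNST_L,L
53,"Caudate Putamen_L",CPu_L,L
54,"Corpus Collosum_L",CoC_L,L
55,"Cortex- Auditory_L",Aud_L,L
56,"Cortex- Cingulate_L",CiC_L,L
57,"Cortex- Entorhinal_L",EC_L,L
58,"Cortex- Frontal Association_L",FrA_L,L
59,"Cortex- Insular_L",In_L,L
60,"Cortex-Medial Prefrontal_L",mPFC_L,L
61,"Cortex- Motor_L",M1_L,L
62,"Cortex- Orbitofrontal_L",OFC_L,L
63,"Cortex- Parietal Association_L",ParA_L,L
64,"Piriform Cortex_L",PC_L,L
65,"Cortex- Retrosplenial_L",RSC_L,L
66,"Cortex- Somatosensory_L",S1_L,L
67,"Cortex- Temporal Association_L",TeA_L,L
68,"Cortex- Visual_L",V1_L,L
69,"Diagonal Band_L",DB_L,L
70,"Globus Pallidus_L",GPa_L,L
71,"Antero-Dorsal Hippocampus_L",adHIP_L,L
72,"Posterior Hippocampus_L",pHIP_L,L
73,"Postero-Dorsal Hippocampus_L",pdHIP_L,L
74,"Hippocampus Subiculum_L",sHIP_L,L
75,"Ventral Hippocampus_L",vHPC_L,L
76,"Lateral Hypothalamus_L",LH_L,L
77,"Medial Hypothalamus_L",MH_L,L
78,"Internal Capsule_L",Ic_L,L
79,"Interstitial Nucleus of the Posterior Limb of the Anterior Commissure_L",IPAC_L,L
80,"Medial Geniculate_L",MG_L,L
81,"Mesencephalic Region_L",MR_L,L
82,"Olfactory Nuclei_L",ON_L,L
83,"Olfactory Tubercle_L",OT_L,L
84,"Periaqueductal Grey_L",PAG_L,L
85,"Pons_L",Pons_L,L
86,"Raphe_L",Raphe_L,L
87,"Septum_L",Septum_L,L
88,"Substantia Innominata_L",SI_L,L
89,"Substantia Nigra_L",SN_L,L
90,"Superior Colliculus_L",SC_L,L
91,"Dorsolateral Thalamus_L",DLT_L,L
92,"Dorsal Midline Thalamus_L",dMT_L,L
93,"Ventromedial Thalamus_L",VMT_L,L
94,"Ventral Pallidum_L",VP_L,L
95,"Ventral Tegmental Area_L",VTA_L,L
96,"Zona Incerta_L",ZI_L,L
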