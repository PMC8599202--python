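id,name,lobe
1,Frontomarginal gyrus and sulcus,frontal
2,Paracentral gyrus and sulcus,frontal
3,Subcentral gyrus and sulcus,frontal
4,Transverse frontopolar gyri,frontal
5,Anterior cingulate gyrus and sulcus,frontal
6,Mid anterior cingulate gyrus and sulcus,frontal
7,Pars opercularis,frontal
8,Pars orbitalis,frontal
9,Pars triangularis,frontal
10,Middle frontal gyrus,frontal
11,Superior frontal gyrus,frontal
12,Orbital gyri,frontal
13,Precentral gyrus,frontal
14,Rectus gyrus,frontal
15,Subcallosal gyrus,frontal
16,Central sulcus,frontal
17,Anterior circular sulcus,frontal
18,Inferior frontal sulcus,frontal
19,Middle frontal sulcus,frontal
20,Superior frontal sulcus,frontal
21,Lateral orbital sulcus,frontal
22,Olfactory sulcus,frontal
23,H-shaped sulcus,frontal
24,Pericallosal sulcus,frontal
25,Inferior precentral sulcus,frontal
26,Superior precentral sulcus,frontal
27,Suborbital sulcus,frontal
28,Mid posterior cingulate gyrus and sulcus,parietal
29,Dorsal posterior cingulate gyrus,parietal
30,Ventral posterior cingulate gyrus,parietal
31,Long insular gyri and central insular sulcus,parietal
32,Short insular gyrus,parietal
33,Angular gyrus,parietal
34,Supramarginal gyrus,parietal
35,Superior parietal gyrus,parietal
36,Postcentral gyrus,parietal
37,Precuneus,parietal
38,Marginal sulcus,parietal
39,Inferior circular sulcus,parietal
40,Jensen sulcus,parietal
41,Intraparietal sulcus,parietal
42,Parieto occipital sulcus,parietal
43,Postcentral sulcus,parietal
44,Subparietal sulcus,parietal
45,Anterior transverse temporal gyri,temporal
46,Lateral superior temporal gyrus,temporal
47,Planum polare,temporal
48,Planum temporale,temporal
49,Inferior temporal gyrus,temporal
50,Middle temporal gyrus,temporal
51,Horizontal lateral fissure,temporal
52,Vertical lateral fissure,temporal
53,Posterior lateral fissure,temporal
54,Temporal pole,temporal
55,Superior circular sulcus,temporal
56,Anterior collateral sulcus,temporal
57,Posterior collateral sulcus,temporal
58,Lateral occipital-temporal sulcus,temporal
59,Medial occipito-temporal and lingual sulci,temporal
60,Inferior temporal sulcus,temporal
61,Superior temporal sulcus,temporal
62,Transverse temporal sulcus,temporal
63,Inferior occipital gyrus and sulcus,occipital
64,Cuneus,occipital
65,Middle occipital gyrus,occipital
66,Superior occipital gyrus,occipital
67,Fusiform gyrus,occipital
68,Lingual gyrus,occipital
69,Parahippocampal gyrus,occipital
70,Occipital pole,occipital
71,Calcarine sulcus,occipital
72,Lunatus sulcus,occipital
73,Superior and transversal occipital sulci,occipital
74,Anterior occipital sulcus,occipital
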