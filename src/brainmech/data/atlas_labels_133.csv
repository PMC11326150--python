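id,name,tissue_class
0,Background,background
4,3rd Ventricle,CSF
11,4th Ventricle,CSF
23,Right Accumbens Area,GM
30,Left Accumbens Area,GM
31,Right Amygdala,GM
32,Left Amygdala,GM
35,Brain Stem,WM
36,Right Caudate,GM
37,Left Caudate,GM
38,Right Cerebellum Exterior,GM
39,Left Cerebellum Exterior,GM
40,Right Cerebellum White Matter,WM
41,Left Cerebellum White Matter,WM
44,Right Cerebral White Matter,WM
45,Left Cerebral White Matter,WM
47,Right Hippocampus,GM
48,Left Hippocampus,GM
49,Right Inf Lat Vent,CSF
50,Left Inf Lat Vent,CSF
51,Right Lateral Ventricle,CSF
52,Left Lateral Ventricle,CSF
55,Right Pallidum,GM
56,Left Pallidum,GM
57,Right Putamen,GM
58,Left Putamen,GM
59,Right Thalamus Proper,GM
60,Left Thalamus Proper,GM
61,Right Ventral DC,GM
62,Left Ventral DC,GM
71,Cerebellar Vermal Lobules I-V,GM
72,Cerebellar Vermal Lobules VI-VII,GM
73,Cerebellar Vermal Lobules VIII-X,GM
75,Left Basal Forebrain,GM
76,Right Basal Forebrain,GM
100,Right ACgG anterior cingulate gyrus,GM
101,Left ACgG anterior cingulate gyrus,GM
102,Right AIns anterior insula,GM
103,Left AIns anterior insula,GM
104,Right AOrG anterior orbital gyrus,GM
105,Left AOrG anterior orbital gyrus,GM
106,Right AnG angular gyrus,GM
107,Left AnG angular gyrus,GM
108,Right Calc calcarine cortex,GM
109,Left Calc calcarine cortex,GM
112,Right CO central operculum,GM
113,Left CO central operculum,GM
114,Right Cun cuneus,GM
115,Left Cun cuneus,GM
116,Right Ent entorhinal area,GM
117,Left Ent entorhinal area,GM
118,Right FO frontal operculum,GM
119,Left FO frontal operculum,GM
120,Right FRP frontal pole,GM
121,Left FRP frontal pole,GM
122,Right FuG fusiform gyrus,GM
123,Left FuG fusiform gyrus,GM
124,Right GRe gyrus rectus,GM
125,Left GRe gyrus rectus,GM
128,Right IOG inferior occipital gyrus,GM
129,Left IOG inferior occipital gyrus,GM
132,Right ITG inferior temporal gyrus,GM
133,Left ITG inferior temporal gyrus,GM
134,Right LiG lingual gyrus,GM
135,Left LiG lingual gyrus,GM
136,Right LOrG lateral orbital gyrus,GM
137,Left LOrG lateral orbital gyrus,GM
138,Right MCgG middle cingulate gyrus,GM
139,Left MCgG middle cingulate gyrus,GM
140,Right MFC medial frontal cortex,GM
141,Left MFC medial frontal cortex,GM
142,Right MFG middle frontal gyrus,GM
143,Left MFG middle frontal gyrus,GM
144,Right MOG middle occipital gyrus,GM
145,Left MOG middle occipital gyrus,GM
146,Right MOrG medial orbital gyrus,GM
147,Left MOrG medial orbital gyrus,GM
148,Right MPoG postcentral gyrus medial segment,GM
149,Left MPoG postcentral gyrus medial segment,GM
150,Right MPrG precentral gyrus medial segment,GM
151,Left MPrG precentral gyrus medial segment,GM
152,Right MSFG superior frontal gyrus medial segment,GM
153,Left MSFG superior frontal gyrus medial segment,GM
154,Right MTG middle temporal gyrus,GM
155,Left MTG middle temporal gyrus,GM
156,Right OCP occipital pole,GM
157,Left OCP occipital pole,GM
160,Right OFuG occipital fusiform gyrus,GM
161,Left OFuG occipital fusiform gyrus,GM
162,Right OpIFG opercular part of the inferior frontal gyrus,GM
163,Left OpIFG opercular part of the inferior frontal gyrus,GM
164,Right OrIFG orbital part of the inferior frontal gyrus,GM
165,Left OrIFG orbital part of the inferior frontal gyrus,GM
166,Right PCgG posterior cingulate gyrus,GM
167,Left PCgG posterior cingulate gyrus,GM
168,Right PCu precuneus,GM
169,Left PCu precuneus,GM
170,Right PHG parahippocampal gyrus,GM
171,Left PHG parahippocampal gyrus,GM
172,Right PIns posterior insula,GM
173,Left PIns posterior insula,GM
174,Right PO parietal operculum,GM
175,Left PO parietal operculum,GM
176,Right PoG postcentral gyrus,GM
177,Left PoG postcentral gyrus,GM
178,Right POrG posterior orbital gyrus,GM
179,Left POrG posterior orbital gyrus,GM
180,Right PP planum polare,GM
181,Left PP planum polare,GM
182,Right PrG precentral gyrus,GM
183,Left PrG precentral gyrus,GM
184,Right PT planum temporale,GM
185,Left PT planum temporale,GM
186,Right SCA subcallosal area,GM
187,Left SCA subcallosal area,GM
190,Right SFG superior frontal gyrus,GM
191,Left SFG superior frontal gyrus,GM
192,Right SMC supplementary motor cortex,GM
193,Left SMC supplementary motor cortex,GM
194,Right SMG supramarginal gyrus,GM
195,Left SMG supramarginal gyrus,GM
196,Right SOG superior occipital gyrus,GM
197,Left SOG superior occipital gyrus,GM
198,Right SPL superior parietal lobule,GM
199,Left SPL superior parietal lobule,GM
200,Right STG superior temporal gyrus,GM
201,Left STG superior temporal gyrus,GM
202,Right TMP temporal pole,GM
203,Left TMP temporal pole,GM
204,Right TrIFG triangular part of the inferior frontal gyrus,GM
205,Left TrIFG triangular part of the inferior frontal gyrus,GM
206,Right TTG transverse temporal gyrus,GM
207,Left TTG transverse temporal gyrus,GM
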