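Participants	Age	Gender	Race	Hemisphere coverage	Number of electrodes	Seizure onset zone	Epilepsy (year)
S01_166	38	F	White	B	176	right hippocampus	2
S02_167	23	F	Mixed	R	168	right posterior insula	4
S03_169	23	M	White	B	186	inferior occipital gyrus	19
S04_170	40	M	Asian	L	116	left posterior inferior temporal lobe	24
S05_171	52	M	Asian	B	252	left lateral temporal and right orbitofrontal region	35
S06_172	47	M	Asian	B	174	mesial temporal and insula	14
S07_176	35	F	White	L	156	left hippocampus	2
S08_177	19	M	White	B	168	hippocampus	4
S09_178	28	M	White	B	252	right anterior temporal lobe	9
S10_181	23	F	White	B	248	right occipital lobe	5
S11_182	37	F	White	B	260	hippocampus	27
S12_183	33	M	White	B	174	right anterior temporal lobe	5
S13_185	36	F	White	B	142	left mesial temporal lobe	26
S14_188	31	M	White	B	122	hippocampus	10
S15_189	27	M	Hispanic	B	184	left posterior insula and left hippocampus	19
S16_190	50	F	White	R	116	right primary somatosensory cortex	4
S17_192	20	M	Hispanic	L	88	left hippocampus	5
S18_193	40	M	Hispanic	B	182	right periventricular nodular heterotopia, right occipital region	30
S19_194	37	M	Hispanic	B	256	left medial hippocampus, right posterior insula and pulvinar	33
S20_195	47	F	Black	B	138	mesial temporal lobe and insula	17
S21_196	40	F	White	B	158	left orbital frontal and left mesial temporal lobe	20
S22_197	20	M	Black	B	214	right supramarginal area	15
S23_198	38	M	Black	B	204	mesial temporal lobe	4
S24_199	36	M	White	B	178	right superior temporal gyrus	20
S25_201	27	M	Hispanic	B	174	mesial temporal lobe	7
S26_202	48	F	Asian	B	194	left mesial occipital area	16
S27_205	48	F	White	B	184	right anterior hippocampus	8
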