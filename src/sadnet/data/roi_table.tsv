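abbrev	name	hemisphere	x	y	z	community	tissue
dlPFCl	Dorsolateral prefrontal cortex	left	-45	24	30	dorsal	cortical
dlPFCr	Dorsolateral prefrontal cortex	right	42	15	39	dorsal	cortical
iFGl	Inferior frontal gyrus	left	-33	22	0	dorsal	cortical
iFGr	Inferior frontal gyrus	right	48	19	0	dorsal	cortical
mSFGl	Medial superior frontal gyrus	left	-7	27	45	dorsal	cortical
mSFGr	Medial superior frontal gyrus	right	8	35	42	dorsal	cortical
IPSl	Intraparietal sulcus	left	-33	-50	41	dorsal	cortical
IPSr	Intraparietal sulcus	right	40	-50	42	dorsal	cortical
PCGl	Postcentral gyrus	left	-33	-24	57	dorsal	cortical
PCGr	Postcentral gyrus	right	54	-21	48	dorsal	cortical
sACCl	Subgenual anterior cingulate cortex	left	-5	22	-7	ventral	cortical
sACCr	Subgenual anterior cingulate cortex	right	15	28	-9	ventral	cortical
mFPl	Medial frontal pole	left	-8	66	6	ventral	cortical
mFPr	Medial frontal pole	right	8	66	9	ventral	cortical
Amyl	Amygdala	left	-27	-12	-15	ventral	subcortical
Amyr	Amygdala	right	27	-9	-18	ventral	subcortical
Hipl	Hippocampus	left	-18	-21	-27	ventral	subcortical
Hipr	Hippocampus	right	21	-21	-15	ventral	subcortical
mOFGl	Medial orbitofrontal gyrus	left	-15	48	-9	ventral	cortical
mOFGr	Medial orbitofrontal gyrus	right	15	48	-9	ventral	cortical
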