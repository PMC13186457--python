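ligand	receptor	co_receptors
MIF	CD74	CXCR4;CD44
CCL2	CCR2
CXCL12	CXCR4
IL34	CSF1R
CSF1	CSF1R
TGFB1	TGFBR1	TGFBR2
SPP1	CD44	ITGAV
APOE	TREM2	TYROBP
PTN	PTPRZ1
MDK	LRP1
IL10	IL10RA	IL10RB
CX3CL1	CX3CR1
GAS6	AXL	MERTK
LGALS9	HAVCR2
CD47	SIRPA
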