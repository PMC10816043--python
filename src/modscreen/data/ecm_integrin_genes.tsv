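subgroup	gene
A	ITGAE
A	ITGB4
A	LAMA4
A	THBS4
C	COL11A2
C	COL4A4
C	COL5A1
C	COL6A2
C	TNC
X11	COL5A1
X11	LAMA5
X11	RELN
X15	COL4A4
X15	FN1
X15	LAMA1
X15	RELN
X15	TNC
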