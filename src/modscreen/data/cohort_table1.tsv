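patient_id	family_id	men1_variant	age	sex	hyperparathyroidism	pituitary	nen	pancreatic_nen	adrenocortical
A2	A	c.1246_1248delGCC/p.Ala416del	59	F	yes	no	no	yes	no
C3	C	c.945delG/p.Tyr316Profs*57	59	M	yes	no	yes	yes	yes
A4	A	c.1246_1248delGCC/p.Ala416del	54	M	yes	yes	no	yes	yes
X5	-	c.866C>A/p.Ala289Glu	59	F	yes	yes	no	no	no
A8	A	c.1246_1248delGCC/p.Ala416del	48	M	yes	yes	no	no	no
C9	C	c.945delG/p.Tyr316Profs*57	33	M	yes	no	no	no	yes
X10	-	c.945delG/p.Tyr316Profs*57	72	F	yes	n/d	yes	yes	no
X11	-	c.416A>G/p.His139Arg	75	F	yes	no	yes	yes	yes
X12	-	c.796C>T/p.Gln266Ter	65	F	yes	no	yes	yes	no
X15	-	c.1256delTGC/p.Leu419del	75	M	yes	yes	yes	no	yes
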