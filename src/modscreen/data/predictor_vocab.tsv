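tool	label	vote
SIFT	tolerated	neutral
SIFT	damaging	damaging
LRT	neutral	neutral
LRT	deleterious	damaging
LRT	unknown	neutral
MutationTaster	polymorphism	neutral
MutationTaster	polymorphism_automatic	neutral
MutationTaster	disease_causing	damaging
MutationTaster	disease_causing_automatic	damaging
Polyphen2_HumDiv	benign	neutral
Polyphen2_HumDiv	possibly_damaging	damaging
Polyphen2_HumDiv	probably_damaging	damaging
Polyphen2_HumVar	benign	neutral
Polyphen2_HumVar	possibly_damaging	damaging
Polyphen2_HumVar	probably_damaging	damaging
MutationAssessor	neutral	neutral
MutationAssessor	low	neutral
MutationAssessor	medium	damaging
MutationAssessor	high	damaging
FATHMM	tolerated	neutral
FATHMM	damaging	damaging
MetaSVM	tolerated	neutral
MetaSVM	damaging	damaging
MetaLR	tolerated	neutral
MetaLR	damaging	damaging
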