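# superfamily	te_class
Copia	Class I LTR
Gypsy	Class I LTR
ERV	Class I LTR
ERV1	Class I LTR
DIRS	Class I LTR
BEL	Class I LTR
L1	Class I non-LTR
L2	Class I non-LTR
CR1	Class I non-LTR
NeSL	Class I non-LTR
R1	Class I non-LTR
RTE	Class I non-LTR
Jockey	Class I non-LTR
Penelope	Class I non-LTR
SINE	Class I non-LTR
hAT	Class II
Mariner/Tc1	Class II
Tc1/Mariner	Class II
Mutator	Class II
MuDR	Class II
CACTA	Class II
EnSpm	Class II
PIF/Harbinger	Class II
Harbinger	Class II
Helitron	Class II
Crypton	Class II
Maverick	Class II
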