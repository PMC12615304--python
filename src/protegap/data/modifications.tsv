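name	mass	residues	position
Acetyl	42.010565	K	anywhere
Methyl	14.015650	KR	anywhere
Dimethyl	28.031300	KR	anywhere
Trimethyl	42.046950	K	anywhere
Phospho	79.966331	STY	anywhere
GlyGly	114.042927	K	anywhere
Succinyl	100.016044	K	anywhere
Malonyl	86.000394	K	anywhere
Glutaryl	114.031694	K	anywhere
Crotonyl	68.026215	K	anywhere
Propionyl	56.026215	K	anywhere
Butyryl	70.041865	K	anywhere
2-Hydroxyisobutyryl	86.036779	K	anywhere
Formyl	27.994915	K	anywhere
Oxidation	15.994915	MW	anywhere
Dioxidation	31.989829	MW	anywhere
Deamidated	0.984016	NQ	anywhere
Nitro	44.985078	Y	anywhere
Sulfo	79.956815	Y	anywhere
Palmitoyl	238.229666	CK	anywhere
Myristoyl	210.198366	K	anywhere
Carbamyl	43.005814	K	anywhere
Carboxymethyl	58.005479	C	anywhere
Methylthio	45.987721	C	anywhere
Gln->pyro-Glu	-17.026549	Q	peptide_nterm
Glu->pyro-Glu	-18.010565	E	peptide_nterm
ADP-Ribosyl	541.061110	RSK	anywhere
Hex	162.052824	ST	anywhere
HexNAc	203.079373	ST	anywhere
Biotin	226.077598	K	anywhere
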