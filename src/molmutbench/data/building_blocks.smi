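# synthetic building-block library: small purchasable-style reagents,
# one per line as SMILES<TAB>name|reagent_class
CCN	ethylamine|amine
CN	methylamine|amine
NCCO	ethanolamine|amine
NCc1ccccc1	benzylamine|amine
C1CCNCC1	piperidine|amine
C1CNCCN1	piperazine|amine
NC1CCCCC1	cyclohexylamine|amine
CC(C)N	isopropylamine|amine
CO	methanol|alcohol
CCO	ethanol|alcohol
OCC1CC1	cyclopropylmethanol|alcohol
OCc1ccccc1	benzyl_alcohol|alcohol
CC(C)O	isopropanol|alcohol
CBr	methyl_bromide|alkyl_halide
CCBr	ethyl_bromide|alkyl_halide
CC(C)Br	isopropyl_bromide|alkyl_halide
BrCc1ccccc1	benzyl_bromide|alkyl_halide
BrCC1CC1	cyclopropylmethyl_bromide|alkyl_halide
CCCCBr	butyl_bromide|alkyl_halide
CS(=O)(=O)Cl	mesyl_chloride|sulfonyl_chloride
Cc1ccc(S(=O)(=O)Cl)cc1	tosyl_chloride|sulfonyl_chloride
O=S(=O)(Cl)c1ccccc1	benzenesulfonyl_chloride|sulfonyl_chloride
CN=C=O	methyl_isocyanate|isocyanate
O=C=Nc1ccccc1	phenyl_isocyanate|isocyanate
CCN=C=O	ethyl_isocyanate|isocyanate
CCN=[N+]=[N-]	ethyl_azide|azide
[N-]=[N+]=NCc1ccccc1	benzyl_azide|azide
CCCN=[N+]=[N-]	propyl_azide|azide
CS	methanethiol|thiol
CCS	ethanethiol|thiol
SCc1ccccc1	benzyl_mercaptan|thiol
SCCO	mercaptoethanol|thiol
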