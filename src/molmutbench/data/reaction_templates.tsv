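amide_coupling	[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(N=*);!$(N#*);!$(N[C,S]=[O,S,N]):3]>>[C:1](=[O:2])[N:3]	amine
ester_formation	[C:1](=[O:2])[OX2H1].[OX2H1:3][CX4:4]>>[C:1](=[O:2])[O:3][C:4]	alcohol
n_alkylation	[NX3;H2,H1;!$(N=*);!$(N#*);!$(N[C,S]=[O,S,N]):1].[CX4:2][Br,Cl,I]>>[N:1][C:2]	alkyl_halide
ether_alkylation	[OX2H1:1].[CX4:2][Br,Cl,I]>>[O:1][C:2]	alkyl_halide
sulfonamide_formation	[NX3;H2,H1;!$(N=*);!$(N#*);!$(N[C,S]=[O,S,N]):1].[SX4:2](=[O:3])(=[O:4])Cl>>[N:1][S:2](=[O:3])(=[O:4])	sulfonyl_chloride
urea_formation	[NX3;H2,H1;!$(N=*);!$(N#*);!$(N[C,S]=[O,S,N]):1].[NX2:2]=[CX2:3]=[OX1:4]>>[N:1][C:3](=[O:4])[N:2]	isocyanate
reductive_amination	[CX3;$([CX3H1][#6]),$([CX3]([#6])[#6]):1]=[OX1:2].[NX3;H2,H1;!$(N=*);!$(N#*);!$(N[C,S]=[O,S,N]):3]>>[C:1][N:3]	amine
epoxide_opening	[CX4;r3:1]1[CX4;r3:2][OX2;r3:3]1.[NX3;H2,H1;!$(N=*);!$(N#*):4]>>[C:1]([N:4])[C:2][O:3]	amine
azide_alkyne_cycloaddition	[CX2:1]#[CX2H1:2].[NX2+0:3](=[N+:4]=[N-:5])[#6]>>[N+0:3]1[N+0:4]=[N+0:5][C:1]=[C:2]1	azide
thiol_ene	[CX3;!$(C=O):1]=[CX3:2].[SX2H1:3]>>[C:1][C:2][S:3]	thiol
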