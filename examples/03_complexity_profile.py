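"""The ten complexity descriptors and indices for familiar molecules.

Prints molecular weight, ring/heteroatom counts, chiral and sp3 carbon
fractions, the degree-based Bertz sum, the Hann proxy, the Wiener index,
QED drug-likeness and the physicochemical complexity score (PCI) for a few
well-known structures.
"""

from molmutbench import complexity_profile, parse_and_sanitize

molecules = {
    "ethanol": "CCO",
    "benzene": "c1ccccc1",
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

fields = ("MW", "NR", "NH", "QCF", "HCF", "BI", "HI", "WI", "QED", "PCI")
print(f"{'molecule':<10}" + "".join(f"{f:>8}" for f in fields))
for name, smiles in molecules.items():
    p = complexity_profile(parse_and_sanitize(smiles, name))
    row = [p.MW, p.NR, p.NH, p.QCF, p.HCF, p.BI, p.HI, p.WI, p.QED, p.PCI]
    print(f"{name:<10}" + "".join(f"{v:>8.2f}" for v in row))

# WI grows quadratically with chain length (it sums all shortest paths);
# BI rewards branching (ln of degree factorials); QED peaks for balanced,
# drug-like property profiles.
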