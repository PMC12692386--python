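"""Why SELFIES-style token mutation never breaks a molecule.

Applies 1000 random single-token edits to MDMA in both string
representations and prints the fraction of mutants that survive full
RDKit sanitization.  The robust grammar embeds valence rules in its
derivation, so every non-empty decode is a real molecule; raw SMILES
editing breaks ring indices, parentheses and valences instead.
"""

import numpy as np

from molmutbench import MutationConfig, parse_and_sanitize
from molmutbench.operators import selfies_token_mutation, smiles_token_mutation

parent = parse_and_sanitize("CC(Cc1ccc2c(c1)OCO2)NC", "MDMA")
rng = np.random.default_rng(0)

for name, fn in [("SF-T", selfies_token_mutation), ("SM-T", smiles_token_mutation)]:
    records = [fn(parent, MutationConfig(operator=name), rng) for _ in range(1000)]
    nonempty = [r for r in records if r.mutant_smiles]
    pct = 100.0 * sum(r.valid for r in nonempty) / len(nonempty)
    print(f"{name}: {pct:.1f}% of {len(nonempty)} non-empty mutants sanitize")

# SF-T prints 100.0%: the grammar guarantee.  SM-T typically lands near
# 20-30%: most single-character SMILES edits are syntactically or
# chemically fatal.
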