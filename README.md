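# molmutbench

Benchmarking **molecular mutation operators** for evolutionary drug design.

Genetic algorithms for de novo molecular design live or die by their
mutation operator: the stochastic map that perturbs a parent molecule into
an offspring. Operators differ wildly in how often they produce chemically
valid molecules, how far they jump in chemical space, how much they disturb
predicted bioactivity, and what they cost. `molmutbench` implements five
operators spanning the main design philosophies and evaluates them under
one standardized protocol, for researchers building evolutionary or
generative molecular-design pipelines who need to choose (or diagnose) an
operator.

## The five operators

| Operator | Representation | Mechanism |
|---|---|---|
| `GB-GA` | molecular graph | primitive valence-checked edits (add/remove atom or bond, change element or bond order, form/cleave ring) with sanitization-rejection resampling |
| `GB-GM` | molecular graph | attachment and ring events sampled from probabilities estimated on a reference corpus |
| `SCC`   | reaction rules | curated click-style reaction-SMARTS templates applied with reagents from a building-block library |
| `SF-T`  | robust token string | insert/replace/delete on a SELFIES-style 15-token alphabet whose grammar guarantees every decode is valid |
| `SM-T`  | raw SMILES string | insert/replace/delete over the 13-character alphabet `FONC()=#12345`; validity is the measured outcome |

Every mutant is judged by one uniform external check — full RDKit
sanitization — regardless of any operator-internal guarantee.

## The protocol and metrics

A seed population (default: 500 synthetic drug-like C/N/O/F molecules
generated from the robust grammar) is crossed with all operators and
mutant budgets k ∈ {1, 3, 5}. Per (operator, k) cell the benchmark
reports:

- **validity** = 100 · valid / (seeds · k), plus wall-clock and mol/s;
- **bioactivity conservation**: mean |ΔpIC50| between parent and mutant
  under a fingerprint random-forest QSAR model (pIC50 = −log₁₀ IC₅₀ [M]);
- **complexity shift**: mean |Δ| of ten descriptors/indices — MW, ring
  count NR, heteroatom count NH, chiral-carbon fraction QCF, sp³ fraction
  HCF, the degree-based Bertz sum BI = Σᵢ ln(deg(i)!), a Hann-style
  proxy HI, the Wiener index WI = ½ ΣᵢΣⱼ dᵢⱼ, QED and the
  physicochemical complexity PCI = logP + (NHA − NHD);
- **diversity**: ECFP4 Tanimoto similarity T(A,B) = |A∩B|/|A∪B|
  (parent–mutant and pairwise CDF), a nine-descriptor table with
  two-component PCA, and histogram Kullback–Leibler divergence
  D(P‖Q) = Σ P ln(P/Q) between original and mutated property
  distributions.

## Worked example

```python
import numpy as np
from molmutbench import MutationConfig, parse_and_sanitize
from molmutbench.operators import selfies_token_mutation, smiles_token_mutation

parent = parse_and_sanitize("CC(Cc1ccc2c(c1)OCO2)NC", "MDMA")
rng = np.random.default_rng(0)
for name, fn in [("SF-T", selfies_token_mutation), ("SM-T", smiles_token_mutation)]:
    recs = [fn(parent, MutationConfig(operator=name), rng) for _ in range(1000)]
    ok = [r for r in recs if r.mutant_smiles]
    print(name, round(100 * sum(r.valid for r in ok) / len(ok), 1), "% valid")
```

prints

```
SF-T 100.0 % valid
SM-T 20.7 % valid
```

SF-T's 100% is the grammar guarantee: valence constraints live in the
token derivation rules, so no sequence of edits can produce an invalid
molecule. SM-T's ~21% shows why raw SMILES editing needs heavy
resampling. The `examples/` directory has one short script per
capability (validity, the five operators, complexity profiles, QSAR
conservation, the full benchmark); run any of them directly, e.g.
`python examples/05_full_benchmark.py`.

A thin CLI wraps the same functions:

```bash
molmutbench seedgen --n 500 --seed 0 --out seeds.smi
molmutbench benchmark --seeds seeds.smi --seed 0 --out report/
```

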