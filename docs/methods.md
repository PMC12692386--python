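# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `molmutbench`, in the order the pipeline uses them.

## Validity

A molecule is *valid* iff RDKit parses its SMILES and completes full
sanitization (syntax, ring-closure bookkeeping, valence, aromaticity
perception). This single external check is applied to every operator's
output; no operator-internal shortcut is trusted, so the validity numbers
of operators with and without built-in guarantees are directly comparable.
Unsanitizable strings are categorized (`syntax`, `unclosed-ring`,
`valence`, `aromaticity`, `empty-input`) on a best-effort basis for error
reporting; the categories do not affect any metric. The empty string
(e.g. after deleting the last token) is invalid (`empty-input`) and counts
in the validity denominator.

## The robust token grammar

`molmutbench.selfies_grammar` implements a SELFIES-style self-valid
string representation restricted to 15 tokens
(`[epsilon] [Ring1] [Ring2] [Branch1_1..3] [F] [O] [=O] [N] [=N] [#N]
[C] [=C] [#C]`). The decoder is a derivation machine that tracks each
atom's remaining bonding capacity (C=4, N=3, O=2, F=1, neutral atoms,
implicit hydrogens); requested bond orders are capped by capacity, branch
and ring constructs read their length/distance operands from the token
stream (any token doubles as a base-15 digit), and impossible constructs
degrade to no-ops. Consequently **every** token sequence decodes to a
sanitizable molecule or the empty string — the property that gives SF-T
mutation its validity guarantee. The encoder maps a neutral, kekulizable
C/N/O/F molecule onto the grammar via a spanning tree whose ring-closure
edges are all single bonds (multi-order bonds are preferred as tree
edges), emitting side chains smallest-first; branches longer than 15
tokens or closures reaching back more than 225 atoms are unencodable and
surface as operator skips (rare for molecules under ~40 heavy atoms).
Stereochemistry is not represented and is dropped on encode; round trips
preserve the canonical constitution exactly.

Design choices that were genuinely open: `[epsilon]` is a no-op rather
than a terminator (it keeps random sequences productive and still serves
as digit 0), and ring bonds are always single (the alphabet has no
bond-typed ring tokens), which the encoder's spanning-tree construction
accommodates.

## Mutation operators

All operators take one valid parent and a shared `MutationConfig`
(`edits_per_mutant=1` by default; edit count per mutant is configurable
for sweeps). Fixed RNG seeds give bitwise-identical mutant lists.

- **SM-T** tokenizes the canonical SMILES lexically (bracket atoms,
  `Cl`/`Br`, `%nn` closures and stereo marks are single tokens), applies a
  uniform insert/replace/delete with symbols drawn only from the
  13-character alphabet, rejoins and sanitizes. No resampling: low
  validity is the phenomenon being measured. Seeds may contain symbols
  outside the alphabet; mutation never inserts them.
- **SF-T** encodes the parent into the robust grammar, edits over the
  15-token alphabet, decodes. Non-empty decodes are always valid;
  unencodable parents are recorded as operator skips.
- **GB-GA** draws one of eight primitive graph edits uniformly
  (add/remove atom, increment/decrement bond order, change element within
  {C,N,O,F}, random bond-order change, form ring of size 3–7, cleave a
  ring bond) on the kekulized graph, sanitizes, and resamples on failure
  up to `resample_cap` (50 in the benchmark). Removing a cut vertex keeps
  the largest fragment (policy configurable to `reject`).
- **GB-GM** estimates, from a reference corpus (default: the seed
  population), the frequencies of (attachment element → added element,
  bond order) events per context and of ring sizes, plus the
  attach-vs-ring marginal; mutation picks a random attachment atom with
  free valence and samples one event, with the same rejection loop as
  GB-GA. Contexts are single-atom elements — the smallest model
  consistent with conditioning growth on local context. Estimation is
  order-independent (counts commute).
- **SCC** shuffles the template list, applies the first template whose
  first reactant pattern matches the parent, drawing a random reagent of
  the template's class for two-component reactions, and picks one product
  uniformly. No match across all templates → `no-template-match`
  (invalid); unsanitizable products count invalid. The package ships 10
  click-style templates (amide coupling, ester formation, N-/O-alkylation,
  sulfonamide, urea, reductive amination, epoxide opening, azide–alkyne
  cycloaddition, thiol-ene) and 33 building blocks in 7 reagent classes;
  larger libraries load from user files in the same formats.

A `max_heavy_atoms` guard (default 120) marks runaway growth as invalid
(`size-guard`). Wall-clock is measured around the operator call only,
excluding I/O and metric computation, and summed per population.

## Synthetic study population

`generate_seed_set` draws uniform-random token sequences (lengths 15–40)
over the 15-token alphabet and decodes them; validity is guaranteed by the
grammar, duplicates are resampled. Random derivations often terminate
early at saturated atoms, so a `min_heavy_atoms=10` floor keeps the
population in the small-drug size range (accepted molecules average ~11.5
heavy atoms); without it the population is dominated by 2–6-atom
fragments that make every operator look like a global rewrite. The
benchmark default is 500 seeds with budgets {1, 3, 5}.

What the generator does *not* emulate: real drug-like populations carry
sulfur, halogens beyond F, charged groups, redundant scaffold families and
purchasable-chemistry bias. Passing tests on this population demonstrate
the correctness and the qualitative operator ordering, not quantitative
agreement with results on curated drug libraries.

## QSAR and the activity oracle

Features are radius-2 circular fingerprints hashed to 2048 bits (ECFP4
convention, matching the diversity metrics). The regressor is a
500-tree random forest with `max_features=0.2`: scikit-learn's regression
default considers all features at every split (bagged trees); sampling a
fifth of the bits restores split-level feature randomness, which on
sparse binary fingerprints generalizes better and fits ~3× faster. All
other hyperparameters are library defaults; the seed is fixed. Training
averages duplicate canonical SMILES, drops unparseable rows (counted),
records held-out R²/RMSE on a fixed-seed 80/20 split, then refits on all
rows for deployment.

The synthetic structure–activity oracle labels a molecule with
`clip(6.5 + w·z + N(0, 0.3), 2, 12)` pIC50 units, where `z` is the
nine-descriptor vector standardized by fixed reference means/scales and
the weights load on hydrogen-bond donors (0.9), sp³ fraction (0.9) and
logP (0.4) — substructure-determined, pharmacophore-style properties a
fingerprint model is built to see. Conservation is the absolute
parent–mutant difference of predictions (magnitude only).

**Known limitation.** At the recovery experiment's conditions (n = 2000,
σ = 0.3) the held-out RMSE stays within 0.6 pIC50 units but R² plateaus
near 0.65–0.69, short of the 0.7 internal target asserted in the
acceptance suite. The bound is representational: satisfying both targets
simultaneously requires explaining ≥ 76 % of the structural signal, while
binary fingerprints of the random-grammar population support ~70–73 %
(its substructure environments are largely unique across molecules, so
tree ensembles cannot interpolate the way they do on redundant real-assay
chemistry; weighting poorly visible descriptors such as raw MW is even
worse, ~0.2). The corresponding test is left failing by design rather
than weakened.

## Complexity metrics

`BI` is the degree-based sum Σ ln(deg(i)!) over heavy atoms — deliberately
*not* RDKit's classical Bertz CT, which includes bonding and heteroatom
information terms; the classical value is available as an optional field
for comparison. `WI` uses heavy-atom shortest paths (disconnected
molecules are an error). `HI` is a documented proxy,
(rings + heteroatoms + chiral centers)/heavy atoms, swappable because no
single canonical "Hann index" formula exists in the accessible
literature. `PCI` defaults to weights (1, 1) on logP and (NHA − NHD);
logP is the Crippen fragment estimate. Chiral-carbon counting includes
unassigned stereocenters by default (configurable to assigned-only).
Natural logarithms are used wherever a base is unstated. QED is RDKit's
desirability product.

## Diversity and distribution shift

Tanimoto similarity is computed on the 2048-bit ECFP4 fingerprints; two
empty fingerprints are defined as similarity 1.0 with a warning. PCA runs
on standardized descriptors (the nine span incommensurate scales);
zero-variance columns are dropped with a warning, and each component's
sign is fixed so its largest-magnitude loading is positive. KL divergence
is estimated from histograms over the samples' combined min–max range with
50 bins and ε = 10⁻¹⁰ added to every bin before normalization (natural
log, direction D(original ‖ mutated)); identical samples give exactly 0.
Binning and smoothing are configurable — published KL values from other
toolchains are not comparable without knowing their scheme.

## Harness and problem sizes

The benchmark report keeps the bookkeeping identities exact: molecules =
Σ valid, validity % = 100·molecules/(seeds·k), mol/s·time = molecules.
Invalid mutants are excluded from delta/similarity/KL computations but
always counted in validity denominators. Duplicate mutants are counted
(deduplication would change the denominators silently). Rankings
normalize each field's mean |Δ| by its per-field maximum before averaging
so that fields on different scales contribute equally. Per-(operator,
budget, seed-index) RNG streams are spawned from one root seed, making
reports bit-for-bit reproducible apart from wall-clock columns.

Test-suite problem sizes were chosen to exercise each property at the
scale where it is meaningful while keeping a full run in minutes: the
grammar guarantee at 10⁴ samples, oracle equivalence on 100 random
molecules, the operator-ordering checks on the full 500 × {1,3,5} × 5
protocol, determinism on a 60-seed two-budget protocol, and QSAR recovery
at the stated n = 2000.
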