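"""The five mutation operators and their shared configuration.

Each operator maps one valid parent molecule to one mutant and records
provenance (attempts, wall-clock, an edit trace).  The operators span three
design philosophies:

* ``GB-GA`` — primitive graph edits (add/remove atom or bond, change
  element or bond order, form/cleave ring) with sanitization-based
  rejection sampling;
* ``GB-GM`` — graph growth by sampling attachment/ring events from
  probabilities estimated on a reference corpus;
* ``SCC`` — reaction-SMARTS templates applied to the parent with reagents
  from a building-block library (click-chemistry style);
* ``SF-T`` — token edits on the robust SELFIES-style string, whose grammar
  guarantees that every non-empty mutant is valid;
* ``SM-T`` — token edits on the raw SMILES string, where broken ring
  indices, parentheses and valences make low validity the expected
  outcome — which is exactly the phenomenon the benchmark measures, so
  SM-T performs no resampling by default.

Validity of every mutant is judged by the uniform external sanitization
check in :mod:`molmutbench.chemio`, never by the operator itself.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from .chemio import (
    Alphabet,
    MoleculeRecord,
    SELFIES_ALPHABET,
    SMILES_ALPHABET,
    TokenKind,
    TokenSequence,
    decode_selfies,
    encode_selfies,
    parse_and_sanitize,
    tokenize_smiles,
)
from .selfies_grammar import EncodeError

__all__ = [
    "OPERATORS",
    "BuildingBlockLibrary",
    "EditProbabilityTable",
    "MutationConfig",
    "MutationRecord",
    "ReactionTemplate",
    "estimate_edit_probabilities",
    "generate_mutants",
    "graph_generative_mutation",
    "graph_mutation_gbga",
    "load_building_blocks",
    "load_reaction_templates",
    "mutate_token_sequence",
    "packaged_building_blocks",
    "packaged_reaction_templates",
    "reaction_mutation",
    "selfies_token_mutation",
    "smiles_token_mutation",
]

OPERATORS = ("GB-GA", "GB-GM", "SCC", "SF-T", "SM-T")

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}


@dataclass(frozen=True)
class MutationConfig:
    """Shared operator configuration.

    ``resample_cap`` bounds sanitization-rejection retries for the graph
    operators (0 disables resampling); token operators measure validity
    directly and do not resample.  ``max_heavy_atoms`` guards against
    runaway growth.
    """

    operator: str = "GB-GA"
    edits_per_mutant: int = 1
    resample_cap: int = 20
    rng_seed: int = 0
    alphabet: Alphabet | None = None
    max_heavy_atoms: int = 120
    gbga_elements: tuple[str, ...] = ("C", "N", "O", "F")
    gbga_ring_sizes: tuple[int, ...] = (3, 4, 5, 6, 7)
    cut_vertex_policy: str = "largest_fragment"  # or "reject"

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise ValueError(f"unknown operator {self.operator!r}")
        if self.edits_per_mutant < 1:
            raise ValueError("edits_per_mutant must be >= 1")
        if self.resample_cap < 0:
            raise ValueError("resample_cap must be >= 0")


@dataclass(frozen=True)
class MutationRecord:
    """Provenance of one mutant."""

    parent_id: str
    operator: str
    mutant_smiles: str
    valid: bool
    elapsed_s: float
    attempts: int
    edit_trace: tuple[str, ...] = ()
    error: str | None = None


# ---------------------------------------------------------------------------
# token-level mutation (shared by SM-T and SF-T)


def mutate_token_sequence(
    seq: TokenSequence, alphabet: Alphabet, rng: np.random.Generator
) -> tuple[TokenSequence, str]:
    """Apply exactly one uniform-random edit (insert / replace / delete).

    The edit kind is uniform over the three kinds, the position uniform over
    valid positions, and inserted or replacement symbols uniform over the
    alphabet (replace never reproduces the symbol it replaces when the
    alphabet has at least two symbols).  Returns the edited sequence and a
    human-readable description of the edit.
    """
    tokens = list(seq.tokens)
    kind = ("insert", "replace", "delete")[rng.integers(3)]
    if kind != "insert" and not tokens:
        raise ValueError(f"cannot {kind} on an empty sequence")
    if kind == "insert":
        pos = int(rng.integers(len(tokens) + 1))
        symbol = alphabet.symbols[rng.integers(len(alphabet.symbols))]
        tokens.insert(pos, symbol)
        trace = f"insert {symbol!r} at {pos}"
    elif kind == "replace":
        pos = int(rng.integers(len(tokens)))
        choices = [s for s in alphabet.symbols if s != tokens[pos]]
        if not choices:
            choices = list(alphabet.symbols)
        symbol = choices[rng.integers(len(choices))]
        trace = f"replace {tokens[pos]!r} with {symbol!r} at {pos}"
        tokens[pos] = symbol
    else:
        pos = int(rng.integers(len(tokens)))
        trace = f"delete {tokens[pos]!r} at {pos}"
        del tokens[pos]
    return TokenSequence(seq.kind, tuple(tokens)), trace


def _finish(parent: MoleculeRecord, cfg: MutationConfig, smiles: str,
            t0: float, attempts: int, trace: list[str],
            error: str | None = None) -> MutationRecord:
    verdict = parse_and_sanitize(smiles)
    if verdict.valid and verdict.mol().GetNumHeavyAtoms() > cfg.max_heavy_atoms:
        verdict = MoleculeRecord(id="", smiles_input=smiles, error="size-guard")
        error = "size-guard"
    elif not verdict.valid and error is None:
        error = verdict.error
    return MutationRecord(
        parent_id=parent.id,
        operator=cfg.operator,
        mutant_smiles=verdict.smiles_canonical if verdict.valid else smiles,
        valid=verdict.valid,
        elapsed_s=time.perf_counter() - t0,
        attempts=attempts,
        edit_trace=tuple(trace),
        error=error,
    )


def smiles_token_mutation(
    record: MoleculeRecord, cfg: MutationConfig, rng: np.random.Generator
) -> MutationRecord:
    """SM-T: edit SMILES tokens, drawing symbols from the 13-char alphabet."""
    _require_valid(record)
    t0 = time.perf_counter()
    alphabet = cfg.alphabet or SMILES_ALPHABET
    seq = tokenize_smiles(record.smiles_canonical)
    trace = []
    for _ in range(cfg.edits_per_mutant):
        if len(seq) == 0:
            break
        seq, step = mutate_token_sequence(seq, alphabet, rng)
        trace.append(step)
    return _finish(record, cfg, seq.join(), t0, 1, trace)


def selfies_token_mutation(
    record: MoleculeRecord, cfg: MutationConfig, rng: np.random.Generator
) -> MutationRecord:
    """SF-T: edit robust-grammar tokens; non-empty decodes are always valid."""
    _require_valid(record)
    t0 = time.perf_counter()
    alphabet = cfg.alphabet or SELFIES_ALPHABET
    try:
        seq = encode_selfies(record.smiles_canonical)
    except EncodeError as exc:
        return MutationRecord(
            parent_id=record.id, operator=cfg.operator, mutant_smiles="",
            valid=False, elapsed_s=time.perf_counter() - t0, attempts=1,
            error=f"operator-skip: {exc}",
        )
    trace = []
    for _ in range(cfg.edits_per_mutant):
        if len(seq) == 0:
            break
        seq, step = mutate_token_sequence(seq, alphabet, rng)
        trace.append(step)
    return _finish(record, cfg, decode_selfies(seq), t0, 1, trace)


# ---------------------------------------------------------------------------
# GB-GA: primitive graph edits with rejection sampling


def _free_valence(atom: Chem.Atom) -> int:
    return max(0, _VALENCE.get(atom.GetSymbol(), 0) - int(atom.GetExplicitValence()))


def _kekulized(record: MoleculeRecord) -> Chem.RWMol:
    mol = record.mol()
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return Chem.RWMol(mol)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if not frags:
        return None
    return max(frags, key=lambda m: m.GetNumAtoms())


_GBGA_EDITS = (
    "add-atom", "remove-atom", "add-bond", "remove-bond",
    "change-element", "change-bond-order", "form-ring", "cleave-ring",
)


def _propose_gbga_edit(
    rw: Chem.RWMol, cfg: MutationConfig, rng: np.random.Generator
) -> tuple[Chem.Mol, str] | None:
    """One primitive edit on a kekulized copy; None when inapplicable."""
    kind = _GBGA_EDITS[rng.integers(len(_GBGA_EDITS))]
    mol = Chem.RWMol(rw)
    n = mol.GetNumAtoms()

    if kind == "add-atom":
        hosts = [a.GetIdx() for a in mol.GetAtoms() if _free_valence(a) >= 1]
        if not hosts:
            return None
        host = hosts[rng.integers(len(hosts))]
        element = cfg.gbga_elements[rng.integers(len(cfg.gbga_elements))]
        new = mol.AddAtom(Chem.Atom(element))
        mol.AddBond(host, new, Chem.BondType.SINGLE)
        return mol.GetMol(), f"add-atom {element} on atom {host}"

    if kind == "remove-atom":
        if n <= 1:
            return None
        idx = int(rng.integers(n))
        symbol = mol.GetAtomWithIdx(idx).GetSymbol()
        mol.RemoveAtom(idx)
        out = mol.GetMol()
        if len(Chem.GetMolFrags(out)) > 1:
            if cfg.cut_vertex_policy == "reject":
                return None
            out = _largest_fragment(out)
            if out is None:
                return None
        return out, f"remove-atom {symbol} at {idx}"

    if kind == "add-bond":  # increment an existing bond's order
        cands = [
            b for b in mol.GetBonds()
            if b.GetBondTypeAsDouble() < 3
            and _free_valence(b.GetBeginAtom()) >= 1
            and _free_valence(b.GetEndAtom()) >= 1
        ]
        if not cands:
            return None
        bond = cands[rng.integers(len(cands))]
        order = int(bond.GetBondTypeAsDouble()) + 1
        bond.SetBondType(_BOND_TYPE[order])
        return mol.GetMol(), f"add-bond -> order {order} on bond {bond.GetIdx()}"

    if kind == "remove-bond":  # decrement a multi-order bond
        cands = [b for b in mol.GetBonds() if b.GetBondTypeAsDouble() > 1]
        if not cands:
            return None
        bond = cands[rng.integers(len(cands))]
        order = int(bond.GetBondTypeAsDouble()) - 1
        bond.SetBondType(_BOND_TYPE[order])
        return mol.GetMol(), f"remove-bond -> order {order} on bond {bond.GetIdx()}"

    if kind == "change-element":
        if n == 0:
            return None
        idx = int(rng.integers(n))
        atom = mol.GetAtomWithIdx(idx)
        old = atom.GetSymbol()
        choices = [
            e for e in cfg.gbga_elements
            if e != old and _VALENCE[e] >= atom.GetExplicitValence()
        ]
        if not choices:
            return None
        element = choices[rng.integers(len(choices))]
        atom.SetAtomicNum(Chem.Atom(element).GetAtomicNum())
        atom.SetNoImplicit(False)
        return mol.GetMol(), f"change-element {old}->{element} at {idx}"

    if kind == "change-bond-order":
        if mol.GetNumBonds() == 0:
            return None
        bond = mol.GetBondWithIdx(int(rng.integers(mol.GetNumBonds())))
        old = int(bond.GetBondTypeAsDouble())
        orders = [o for o in (1, 2, 3) if o != old]
        order = orders[rng.integers(len(orders))]
        bond.SetBondType(_BOND_TYPE[order])
        return mol.GetMol(), f"change-bond-order {old}->{order} on bond {bond.GetIdx()}"

    if kind == "form-ring":
        if n < 3:
            return None
        dist = Chem.GetDistanceMatrix(Chem.Mol(rw))
        pairs = [
            (i, j)
            for i in range(n)
            for j in range(i + 1, n)
            if (dist[i, j] + 1) in cfg.gbga_ring_sizes
            and mol.GetBondBetweenAtoms(i, j) is None
            and _free_valence(mol.GetAtomWithIdx(i)) >= 1
            and _free_valence(mol.GetAtomWithIdx(j)) >= 1
        ]
        if not pairs:
            return None
        i, j = pairs[rng.integers(len(pairs))]
        mol.AddBond(i, j, Chem.BondType.SINGLE)
        return mol.GetMol(), f"form-ring size {int(dist[i, j]) + 1} between {i},{j}"

    # cleave-ring: delete a bond that lies in a ring (molecule stays connected)
    ring_bonds = [b for b in mol.GetBonds() if b.IsInRing()]
    if not ring_bonds:
        return None
    bond = ring_bonds[rng.integers(len(ring_bonds))]
    a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    mol.RemoveBond(a, b)
    return mol.GetMol(), f"cleave-ring bond {a}-{b}"


def _sanitize_candidate(candidate: Chem.Mol) -> str | None:
    try:
        mol = Chem.Mol(candidate)
        Chem.SanitizeMol(mol)
        smiles = Chem.MolToSmiles(mol)
    except Exception:
        return None
    # the uniform external check is authoritative
    return smiles if parse_and_sanitize(smiles).valid else None


def graph_mutation_gbga(
    record: MoleculeRecord, cfg: MutationConfig, rng: np.random.Generator
) -> MutationRecord:
    """GB-GA: one primitive graph edit, resampled until sanitization passes."""
    _require_valid(record)
    t0 = time.perf_counter()
    rw = _kekulized(record)
    last_smiles = ""
    for attempt in range(1, cfg.resample_cap + 2):
        proposal = _propose_gbga_edit(rw, cfg, rng)
        if proposal is None:
            continue
        candidate, trace = proposal
        for _ in range(cfg.edits_per_mutant - 1):
            extra = _propose_gbga_edit(Chem.RWMol(candidate), cfg, rng)
            if extra is None:
                break
            candidate, step = extra
            trace += "; " + step
        smiles = _sanitize_candidate(candidate)
        if smiles is not None:
            if candidate.GetNumAtoms() > cfg.max_heavy_atoms:
                return _finish(record, cfg, smiles, t0, attempt, [trace],
                               error="size-guard")
            return _finish(record, cfg, smiles, t0, attempt, [trace])
        last_smiles = Chem.MolToSmiles(candidate, canonical=False)
    return MutationRecord(
        parent_id=record.id, operator=cfg.operator, mutant_smiles=last_smiles,
        valid=False, elapsed_s=time.perf_counter() - t0,
        attempts=cfg.resample_cap + 1, error="resample-exhausted",
    )


# ---------------------------------------------------------------------------
# GB-GM: corpus-estimated edit probabilities


@dataclass(frozen=True)
class EditProbabilityTable:
    """Attachment and ring-formation frequencies estimated from a corpus.

    ``attach[element]`` maps (added element, bond order) to a probability
    (normalized within the context); ``ring_sizes`` maps ring size to a
    probability; ``kind`` holds the marginal attach-vs-ring probabilities.
    """

    attach: dict[str, dict[tuple[str, int], float]]
    ring_sizes: dict[int, float]
    kind: dict[str, float]

    def contexts(self) -> set[str]:
        return set(self.attach)


def estimate_edit_probabilities(
    corpus: list[MoleculeRecord],
) -> EditProbabilityTable:
    """Count (attachment element, added element, bond order) events and ring
    sizes over every bond and ring of the corpus; order-independent."""
    valid = [r for r in corpus if r.valid]
    if not valid:
        raise ValueError("corpus contains no valid molecules")
    attach_counts: dict[str, dict[tuple[str, int], int]] = {}
    ring_counts: dict[int, int] = {}
    n_attach = 0
    n_ring = 0
    for rec in valid:
        mol = rec.mol()
        Chem.Kekulize(mol, clearAromaticFlags=True)
        for bond in mol.GetBonds():
            order = int(bond.GetBondTypeAsDouble())
            for ctx_atom, added in (
                (bond.GetBeginAtom(), bond.GetEndAtom()),
                (bond.GetEndAtom(), bond.GetBeginAtom()),
            ):
                ctx = ctx_atom.GetSymbol()
                event = (added.GetSymbol(), order)
                attach_counts.setdefault(ctx, {})
                attach_counts[ctx][event] = attach_counts[ctx].get(event, 0) + 1
                n_attach += 1
        for ring in mol.GetRingInfo().AtomRings():
            ring_counts[len(ring)] = ring_counts.get(len(ring), 0) + 1
            n_ring += 1
    attach = {
        ctx: {ev: c / sum(events.values()) for ev, c in sorted(events.items())}
        for ctx, events in sorted(attach_counts.items())
    }
    total_rings = sum(ring_counts.values())
    ring_sizes = {s: c / total_rings for s, c in sorted(ring_counts.items())}
    total = n_attach + n_ring
    kind = {"attach": n_attach / total, "ring": n_ring / total}
    return EditProbabilityTable(attach=attach, ring_sizes=ring_sizes, kind=kind)


def _sample_categorical(
    items: list, probs: list[float], rng: np.random.Generator
):
    idx = rng.choice(len(items), p=np.asarray(probs) / np.sum(probs))
    return items[int(idx)]


def graph_generative_mutation(
    record: MoleculeRecord,
    table: EditProbabilityTable,
    cfg: MutationConfig,
    rng: np.random.Generator,
) -> MutationRecord:
    """GB-GM: grow the parent by sampling an attachment or ring event from
    corpus-estimated probabilities, with sanitization-rejection resampling."""
    _require_valid(record)
    t0 = time.perf_counter()
    rw = _kekulized(record)
    hosts = [
        a.GetIdx() for a in rw.GetAtoms()
        if _free_valence(a) >= 1 and a.GetSymbol() in table.contexts()
    ]
    if not hosts:
        return MutationRecord(
            parent_id=record.id, operator=cfg.operator, mutant_smiles="",
            valid=False, elapsed_s=time.perf_counter() - t0, attempts=1,
            error="operator-skip: no applicable context",
        )
    for attempt in range(1, cfg.resample_cap + 2):
        mol = Chem.RWMol(rw)
        host = hosts[rng.integers(len(hosts))]
        kind = _sample_categorical(
            list(table.kind), list(table.kind.values()), rng)
        if kind == "attach":
            ctx = mol.GetAtomWithIdx(host).GetSymbol()
            events = table.attach[ctx]
            element, order = _sample_categorical(
                list(events), list(events.values()), rng)
            if order > _free_valence(mol.GetAtomWithIdx(host)) or order > _VALENCE[element]:
                continue
            new = mol.AddAtom(Chem.Atom(element))
            mol.AddBond(host, new, _BOND_TYPE[order])
            trace = f"attach {element} (order {order}) on atom {host}"
        else:
            size = _sample_categorical(
                list(table.ring_sizes), list(table.ring_sizes.values()), rng)
            dist = Chem.GetDistanceMatrix(Chem.Mol(rw))
            partners = [
                j for j in range(mol.GetNumAtoms())
                if dist[host, j] == size - 1
                and mol.GetBondBetweenAtoms(host, j) is None
                and _free_valence(mol.GetAtomWithIdx(j)) >= 1
                and _free_valence(mol.GetAtomWithIdx(host)) >= 1
            ]
            if not partners:
                continue
            j = partners[rng.integers(len(partners))]
            mol.AddBond(host, j, Chem.BondType.SINGLE)
            trace = f"form-ring size {size} between {host},{j}"
        smiles = _sanitize_candidate(mol.GetMol())
        if smiles is not None:
            if mol.GetNumAtoms() > cfg.max_heavy_atoms:
                return _finish(record, cfg, smiles, t0, attempt, [trace],
                               error="size-guard")
            return _finish(record, cfg, smiles, t0, attempt, [trace])
    return MutationRecord(
        parent_id=record.id, operator=cfg.operator, mutant_smiles="",
        valid=False, elapsed_s=time.perf_counter() - t0,
        attempts=cfg.resample_cap + 1, error="resample-exhausted",
    )


# ---------------------------------------------------------------------------
# SCC: reaction-template mutation


@dataclass(frozen=True)
class ReactionTemplate:
    """A curated reaction-SMARTS template; the first reactant slot is the
    parent molecule."""

    name: str
    smarts: str
    reagent_class: str | None = None

    def reaction(self) -> AllChem.ChemicalReaction:
        rxn = AllChem.ReactionFromSmarts(self.smarts)
        if rxn is None or rxn.GetNumReactantTemplates() < 1:
            raise ValueError(f"template {self.name!r} does not compile")
        return rxn


class BuildingBlockLibrary:
    """Reagent SMILES grouped by reagent class; every reagent sanitizes."""

    def __init__(self, by_class: dict[str, list[str]]):
        self.by_class: dict[str, list[str]] = {}
        for cls, smiles_list in by_class.items():
            mols = []
            for smi in smiles_list:
                rec = parse_and_sanitize(smi)
                if not rec.valid:
                    raise ValueError(f"reagent {smi!r} does not sanitize")
                mols.append(rec.smiles_canonical)
            self.by_class[cls] = mols

    def sample(self, reagent_class: str, rng: np.random.Generator) -> str | None:
        pool = self.by_class.get(reagent_class)
        if not pool:
            return None
        return pool[rng.integers(len(pool))]


def load_reaction_templates(path: str | Path) -> list[ReactionTemplate]:
    """Read ``name<TAB>reaction-SMARTS<TAB>reagent_class`` lines."""
    templates = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        name, smarts = parts[0], parts[1]
        reagent_class = parts[2] if len(parts) > 2 and parts[2] else None
        tpl = ReactionTemplate(name, smarts, reagent_class)
        tpl.reaction()  # fail fast on uncompilable SMARTS
        templates.append(tpl)
    return templates


def load_building_blocks(path: str | Path) -> BuildingBlockLibrary:
    """Read a .smi file whose id column is ``name|reagent_class``."""
    by_class: dict[str, list[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, _, label = line.partition("\t")
        cls = label.rsplit("|", 1)[-1] if "|" in label else "default"
        by_class.setdefault(cls, []).append(smiles.strip())
    return BuildingBlockLibrary(by_class)


def packaged_reaction_templates() -> list[ReactionTemplate]:
    with resources.as_file(
        resources.files("molmutbench.data") / "reaction_templates.tsv"
    ) as p:
        return load_reaction_templates(p)


def packaged_building_blocks() -> BuildingBlockLibrary:
    with resources.as_file(
        resources.files("molmutbench.data") / "building_blocks.smi"
    ) as p:
        return load_building_blocks(p)


_RXN_CACHE: dict[str, AllChem.ChemicalReaction] = {}


def _compiled(template: ReactionTemplate) -> AllChem.ChemicalReaction:
    rxn = _RXN_CACHE.get(template.smarts)
    if rxn is None:
        rxn = template.reaction()
        _RXN_CACHE[template.smarts] = rxn
    return rxn


def reaction_mutation(
    record: MoleculeRecord,
    templates: list[ReactionTemplate],
    library: BuildingBlockLibrary,
    cfg: MutationConfig,
    rng: np.random.Generator,
) -> MutationRecord:
    """SCC: apply the first matching template (shuffled order) with a random
    reagent from its class; one product drawn uniformly from the product set."""
    _require_valid(record)
    if not templates:
        raise ValueError("at least one reaction template is required")
    t0 = time.perf_counter()
    parent_mol = record.mol()
    order = rng.permutation(len(templates))
    for ti in order:
        template = templates[int(ti)]
        rxn = _compiled(template)
        if not parent_mol.HasSubstructMatch(rxn.GetReactantTemplate(0)):
            continue
        reactants = [parent_mol]
        reagent_smiles = None
        if rxn.GetNumReactantTemplates() == 2:
            reagent_smiles = library.sample(template.reagent_class, rng)
            if reagent_smiles is None:
                continue
            reagent = Chem.MolFromSmiles(reagent_smiles)
            if not reagent.HasSubstructMatch(rxn.GetReactantTemplate(1)):
                continue
            reactants.append(reagent)
        product_sets = rxn.RunReactants(tuple(reactants))
        products = [p for ps in product_sets for p in ps]
        if not products:
            continue
        product = products[rng.integers(len(products))]
        try:
            Chem.SanitizeMol(product)
            smiles = Chem.MolToSmiles(product)
        except Exception:
            smiles = Chem.MolToSmiles(product, canonical=False)
        trace = f"{template.name}" + (
            f" with reagent {reagent_smiles}" if reagent_smiles else ""
        )
        return _finish(record, cfg, smiles, t0, 1, [trace])
    return MutationRecord(
        parent_id=record.id, operator=cfg.operator, mutant_smiles="",
        valid=False, elapsed_s=time.perf_counter() - t0, attempts=1,
        error="no-template-match",
    )


# ---------------------------------------------------------------------------
# dispatcher


def _require_valid(record: MoleculeRecord) -> None:
    if not record.valid:
        raise ValueError(f"parent record {record.id!r} is invalid")


def mutate_once(
    record: MoleculeRecord,
    cfg: MutationConfig,
    rng: np.random.Generator,
    *,
    table: EditProbabilityTable | None = None,
    templates: list[ReactionTemplate] | None = None,
    library: BuildingBlockLibrary | None = None,
) -> MutationRecord:
    """Apply the operator named in ``cfg`` once."""
    if cfg.operator == "SM-T":
        return smiles_token_mutation(record, cfg, rng)
    if cfg.operator == "SF-T":
        return selfies_token_mutation(record, cfg, rng)
    if cfg.operator == "GB-GA":
        return graph_mutation_gbga(record, cfg, rng)
    if cfg.operator == "GB-GM":
        if table is None:
            raise ValueError("GB-GM requires an EditProbabilityTable")
        return graph_generative_mutation(record, table, cfg, rng)
    if cfg.operator == "SCC":
        templates = templates if templates is not None else packaged_reaction_templates()
        library = library if library is not None else packaged_building_blocks()
        return reaction_mutation(record, templates, library, cfg, rng)
    raise ValueError(f"unknown operator {cfg.operator!r}")


def generate_mutants(
    record: MoleculeRecord,
    cfg: MutationConfig,
    k: int,
    rng: np.random.Generator,
    **operator_inputs,
) -> list[MutationRecord]:
    """Exactly ``k`` independent mutants of one parent.

    Operator skips are returned as invalid records so the list length is
    always ``k``; duplicates among the mutants are kept (deduplication is a
    reporting option, not an operator concern).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return [mutate_once(record, cfg, rng, **operator_inputs) for _ in range(k)]
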