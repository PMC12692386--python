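"""A self-valid token grammar for C/N/O/F chemistry.

This module implements a SELFIES-style robust molecular string
representation restricted to the 15-token alphabet used throughout the
benchmark::

    [epsilon] [Ring1] [Ring2] [Branch1_1] [Branch1_2] [Branch1_3]
    [F] [O] [=O] [N] [=N] [#N] [C] [=C] [#C]

The defining property is that *every* token sequence over this alphabet
decodes to a sanitizable molecule (or to the empty string): valence
constraints are enforced during derivation, so no sequence of edits on the
token level can produce an invalid structure.  This is the mechanism that
gives SELFIES-token mutation its validity guarantee, in contrast to raw
SMILES editing where ring indices and parentheses break easily.

Derivation rules
----------------
The decoder is a state machine that tracks, for every derived atom, its
remaining bonding capacity (C=4, N=3, O=2, F=1; neutral atoms, implicit
hydrogens fill the slack):

* An atom token ``[C]``/``[=C]``/``[#C]`` etc. derives a new atom bonded to
  the previous atom in the chain.  The realised bond order is
  ``min(requested, capacity(prev), valence(new))`` — a ``#`` bond request
  next to an oxygen silently degrades to a single bond instead of failing.
  If the previous atom has no capacity left, derivation of the current
  chain stops (remaining tokens are discarded), mirroring the "the rest of
  the string is dominated" robustness convention.
* ``[Branch1_L]`` (L in 1..3) reads the next token as a number Q via the
  index table below and derives the following Q+1 tokens as a side chain
  attached to the current atom with requested bond order L.
* ``[Ring1]`` reads one number token Q and bonds the current atom to the
  atom derived Q+1 positions earlier (single bond); ``[Ring2]`` reads two
  number tokens (base-15).  Ring bonds that would duplicate an existing
  bond, self-bond, or exceed either atom's capacity are no-ops.
* ``[epsilon]`` is a no-op (it still counts toward branch lengths and can
  serve as a number token).

Every token doubles as a number through its position in ``ALPHABET``
(``[epsilon]`` = 0 ... ``[#C]`` = 14); multi-token numbers are big-endian
base-15.

The encoder maps a kekulizable, neutral molecule over {C,N,O,F} onto this
grammar by building a spanning tree whose co-tree (ring-closure) edges are
all single bonds, emitting branches smallest-first so the main chain
carries the bulk of the molecule.  ``decode(encode(m))`` reproduces the
canonical molecule exactly (stereochemistry is not represented and is
dropped on encode).  Molecules outside the supported chemistry — charges,
radicals, elements beyond C/N/O/F, branches longer than 15 tokens, ring
closures reaching back more than 225 atoms — raise :class:`EncodeError`.
"""

from __future__ import annotations

import re

from rdkit import Chem
from rdkit.Chem import rdmolops

__all__ = [
    "ALPHABET",
    "ATOM_TOKENS",
    "EncodeError",
    "decode",
    "encode",
    "split_tokens",
]

#: Canonical token order; a token's position is its numeric value when it is
#: read as a branch-length or ring-distance digit.
ALPHABET: tuple[str, ...] = (
    "[epsilon]",
    "[Ring1]",
    "[Ring2]",
    "[Branch1_1]",
    "[Branch1_2]",
    "[Branch1_3]",
    "[F]",
    "[O]",
    "[=O]",
    "[N]",
    "[=N]",
    "[#N]",
    "[C]",
    "[=C]",
    "[#C]",
)

_INDEX = {tok: i for i, tok in enumerate(ALPHABET)}
_BASE = len(ALPHABET)

# atom token -> (element, requested bond order to the previous atom)
ATOM_TOKENS: dict[str, tuple[str, int]] = {
    "[F]": ("F", 1),
    "[O]": ("O", 1),
    "[=O]": ("O", 2),
    "[N]": ("N", 1),
    "[=N]": ("N", 2),
    "[#N]": ("N", 3),
    "[C]": ("C", 1),
    "[=C]": ("C", 2),
    "[#C]": ("C", 3),
}

_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}
_BOND_PREFIX = {1: "", 2: "=", 3: "#"}

_TOKEN_RE = re.compile(r"\[[^\[\]]*\]")


class EncodeError(ValueError):
    """Molecule cannot be expressed in the restricted grammar."""


def split_tokens(selfies: str) -> list[str]:
    """Split a bracketed token string into individual tokens.

    Raises ``ValueError`` when the string is not a concatenation of
    bracketed tokens.
    """
    tokens = _TOKEN_RE.findall(selfies)
    if "".join(tokens) != selfies:
        raise ValueError(f"not a well-formed token string: {selfies!r}")
    return tokens


def _token_value(token: str) -> int:
    return _INDEX.get(token, 0)


class _Decoder:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0
        self.mol = Chem.RWMol()
        self.capacity: list[int] = []  # remaining bond capacity per atom idx

    def _next(self) -> str | None:
        if self.pos >= len(self.tokens):
            return None
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def _read_number(self, n_digits: int) -> int | None:
        value = 0
        for _ in range(n_digits):
            tok = self._next()
            if tok is None:
                return None
            value = value * _BASE + _token_value(tok)
        return value

    def _new_atom(self, element: str) -> int:
        idx = self.mol.AddAtom(Chem.Atom(element))
        self.capacity.append(_VALENCE[element])
        return idx

    def _bond(self, a: int, b: int, order: int) -> None:
        self.mol.AddBond(a, b, _BOND_TYPE[order])
        self.capacity[a] -= order
        self.capacity[b] -= order

    def derive(self, end: int | None = None, attach: int | None = None,
               pending_order: int = 1) -> None:
        """Derive a chain until ``end`` (stream position); ``attach`` is the
        atom the first derived atom bonds to."""
        current = attach
        pending = pending_order if attach is not None else 0
        while True:
            if end is not None and self.pos >= end:
                return
            tok = self._next()
            if tok is None:
                return
            if tok == "[epsilon]":
                continue
            if tok in ATOM_TOKENS:
                element, requested = ATOM_TOKENS[tok]
                if current is None:
                    current = self._new_atom(element)
                    pending = 0
                    continue
                order = max(pending, requested) if pending else requested
                order = min(order, self.capacity[current], _VALENCE[element])
                pending = 0
                if order < 1:
                    # chain saturated: discard the remainder of this scope
                    self.pos = end if end is not None else len(self.tokens)
                    return
                new = self._new_atom(element)
                self._bond(current, new, order)
                current = new
                continue
            if tok in ("[Ring1]", "[Ring2]"):
                n = self._read_number(1 if tok == "[Ring1]" else 2)
                if n is None or current is None:
                    continue
                partner = current - (n + 1)
                if (
                    partner < 0
                    or partner == current
                    or self.capacity[current] < 1
                    or self.capacity[partner] < 1
                    or self.mol.GetBondBetweenAtoms(current, partner) is not None
                ):
                    continue
                self._bond(current, partner, 1)
                continue
            if tok in ("[Branch1_1]", "[Branch1_2]", "[Branch1_3]"):
                branch_order = int(tok[-2])
                q = self._read_number(1)
                if q is None:
                    continue
                length = q + 1
                branch_end = min(self.pos + length, len(self.tokens))
                if end is not None:
                    branch_end = min(branch_end, end)
                if current is None or self.capacity[current] < 1:
                    self.pos = branch_end  # skip unattachable branch
                    continue
                self.derive(end=branch_end, attach=current,
                            pending_order=branch_order)
                self.pos = branch_end
                continue
            # unknown token: ignored (robustness over strictness)
            continue


def decode(tokens: list[str] | str) -> str:
    """Decode a token sequence to a canonical SMILES string.

    Any sequence of alphabet tokens yields a sanitizable molecule; the
    empty sequence (or one deriving no atoms) yields ``""``.
    """
    if isinstance(tokens, str):
        tokens = split_tokens(tokens)
    dec = _Decoder(list(tokens))
    dec.derive()
    if dec.mol.GetNumAtoms() == 0:
        return ""
    mol = dec.mol.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


# ---------------------------------------------------------------------------
# encoding


def _number_tokens(value: int, n_digits: int) -> list[str]:
    digits = []
    for _ in range(n_digits):
        digits.append(ALPHABET[value % _BASE])
        value //= _BASE
    return digits[::-1]


def _spanning_tree(mol: Chem.Mol) -> tuple[set[int], list[tuple[int, int]]]:
    """Union-find spanning tree preferring multi-order bonds as tree edges,
    so every ring-closure (co-tree) edge is a single bond."""
    parent = list(range(mol.GetNumAtoms()))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    bonds = sorted(
        mol.GetBonds(),
        key=lambda b: -int(b.GetBondTypeAsDouble()),
    )
    tree: set[int] = set()
    closures: list[tuple[int, int]] = []
    for bond in bonds:
        ra, rb = find(bond.GetBeginAtomIdx()), find(bond.GetEndAtomIdx())
        if ra != rb:
            parent[ra] = rb
            tree.add(bond.GetIdx())
        else:
            if bond.GetBondTypeAsDouble() != 1.0:
                raise EncodeError("ring closure on a multi-order bond")
            closures.append((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return tree, closures


def _prepare(mol: Chem.Mol) -> Chem.Mol:
    mol = Chem.Mol(mol)
    Chem.RemoveStereochemistry(mol)
    mol = Chem.RemoveHs(mol)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in _VALENCE:
            raise EncodeError(f"unsupported element {atom.GetSymbol()}")
        if atom.GetFormalCharge() != 0:
            raise EncodeError("charged atoms are not representable")
        if atom.GetNumRadicalElectrons() != 0:
            raise EncodeError("radicals are not representable")
        if atom.GetIsotope() != 0:
            raise EncodeError("isotope labels are not representable")
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        if atom.GetTotalValence() > _VALENCE[atom.GetSymbol()]:
            raise EncodeError("valence beyond the grammar's defaults")
    return mol


def encode(smiles_or_mol: str | Chem.Mol) -> list[str]:
    """Encode a molecule into the token grammar.

    Raises :class:`EncodeError` for molecules the restricted alphabet cannot
    express; callers treat that as an operator skip.
    """
    if isinstance(smiles_or_mol, str):
        mol = Chem.MolFromSmiles(smiles_or_mol)
        if mol is None:
            raise EncodeError(f"unparseable SMILES: {smiles_or_mol!r}")
    else:
        mol = smiles_or_mol
    mol = _prepare(mol)
    n = mol.GetNumAtoms()
    if n == 0:
        return []
    if len(Chem.GetMolFrags(mol)) > 1:
        raise EncodeError("disconnected molecules are not representable")

    tree, closures = _spanning_tree(mol)
    children: dict[int, list[int]] = {i: [] for i in range(n)}
    order_of: dict[tuple[int, int], int] = {}
    for bond in mol.GetBonds():
        a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        o = int(bond.GetBondTypeAsDouble())
        order_of[(a, b)] = order_of[(b, a)] = o

    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for bond in mol.GetBonds():
        if bond.GetIdx() in tree:
            a, b = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            adj[a].append(b)
            adj[b].append(a)

    # subtree atom counts for smallest-branch-first ordering
    size = [1] * n
    seen = [False] * n
    post: list[int] = []
    stack = [(0, -1, False)]
    while stack:
        node, par, done = stack.pop()
        if done:
            for nb in adj[node]:
                if nb != par:
                    size[node] += size[nb]
            continue
        seen[node] = True
        stack.append((node, par, True))
        for nb in adj[node]:
            if nb != par:
                stack.append((nb, node, False))

    closure_at: dict[int, list[int]] = {}
    for a, b in closures:
        closure_at.setdefault(a, []).append(b)
        closure_at.setdefault(b, []).append(a)

    emit_pos: dict[int, int] = {}
    tokens: list[str] = []

    def atom_token(idx: int, order: int) -> str:
        return f"[{_BOND_PREFIX[order]}{mol.GetAtomWithIdx(idx).GetSymbol()}]"

    def emit(node: int, par: int, order: int) -> list[str]:
        out = [atom_token(node, order)]
        emit_pos[node] = len(emit_pos)
        for partner in closure_at.get(node, ()):
            if partner in emit_pos and partner != node:
                dist = emit_pos[node] - emit_pos[partner]
                if dist < 1:
                    continue
                if dist <= _BASE:
                    out += ["[Ring1]"] + _number_tokens(dist - 1, 1)
                elif dist <= _BASE * _BASE:
                    out += ["[Ring2]"] + _number_tokens(dist - 1, 2)
                else:
                    raise EncodeError("ring closure reaches too far back")
        kids = sorted((nb for nb in adj[node] if nb != par),
                      key=lambda k: (size[k], k))
        for i, kid in enumerate(kids):
            kid_tokens = emit(kid, node, order_of[(node, kid)])
            if i < len(kids) - 1:
                if len(kid_tokens) > _BASE:
                    raise EncodeError("branch longer than the grammar allows")
                out += [f"[Branch1_{order_of[(node, kid)]}]"]
                out += _number_tokens(len(kid_tokens) - 1, 1)
            out += kid_tokens
        return out

    tokens = emit(0, -1, 1)
    return tokens
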