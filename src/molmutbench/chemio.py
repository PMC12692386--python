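"""Molecule parsing, sanitization-based validity, tokenization and file I/O.

Validity throughout the benchmark is defined by one uniform external check:
a SMILES string is *valid* iff RDKit can parse it and run full sanitization
(syntax, ring closure, valence, aromaticity perception).  Every mutation
operator's output is pushed through the same check regardless of any
internal guarantee the operator claims.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

from rdkit import Chem
from rdkit import RDLogger

from . import selfies_grammar

RDLogger.DisableLog("rdApp.*")  # malformed inputs are expected, not news

__all__ = [
    "Alphabet",
    "MoleculeRecord",
    "SELFIES_ALPHABET",
    "SMILES_ALPHABET",
    "TokenKind",
    "TokenSequence",
    "canonicalize",
    "decode_selfies",
    "encode_selfies",
    "parse_and_sanitize",
    "read_smiles_file",
    "read_table",
    "tokenize_smiles",
    "write_smiles_file",
    "write_table",
]


class TokenKind(str, Enum):
    SMILES = "SMILES"
    SELFIES = "SELFIES"


@dataclass(frozen=True)
class MoleculeRecord:
    """One molecule with its input SMILES and validity verdict."""

    id: str
    smiles_input: str
    smiles_canonical: str | None = None
    valid: bool = False
    error: str | None = None

    def __post_init__(self) -> None:
        if self.valid and self.smiles_canonical is None:
            raise ValueError("valid record requires a canonical SMILES")
        if not self.valid and self.error is None:
            raise ValueError("invalid record requires an error category")

    def mol(self) -> Chem.Mol:
        if not self.valid:
            raise ValueError(f"record {self.id!r} is invalid ({self.error})")
        return Chem.MolFromSmiles(self.smiles_canonical)


@dataclass(frozen=True)
class TokenSequence:
    kind: TokenKind
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)

    def join(self) -> str:
        return "".join(self.tokens)


@dataclass(frozen=True)
class Alphabet:
    kind: TokenKind
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("alphabet must be non-empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")


#: The 13-character SMILES mutation alphabet.
SMILES_ALPHABET = Alphabet(
    TokenKind.SMILES,
    ("F", "O", "N", "C", "(", ")", "=", "#", "1", "2", "3", "4", "5"),
)

#: The 15-token SELFIES mutation alphabet.
SELFIES_ALPHABET = Alphabet(TokenKind.SELFIES, selfies_grammar.ALPHABET)


_RING_UNCLOSED = re.compile(r"unclosed ring|[Rr]ing closure|duplicated ring")


def _categorize(smiles: str) -> str:
    """Best-effort error category for an unsanitizable SMILES."""
    mol = Chem.MolFromSmiles(smiles, sanitize=False)
    if mol is None:
        # lexical/structural failure: distinguish ring-closure bookkeeping
        digits = re.sub(r"\[[^\]]*\]|%\d{2}", "", smiles)
        counts: dict[str, int] = {}
        for ch in digits:
            if ch.isdigit():
                counts[ch] = counts.get(ch, 0) + 1
        if any(c % 2 for c in counts.values()):
            return "unclosed-ring"
        return "syntax"
    try:
        Chem.SanitizeMol(mol)
    except Chem.AtomValenceException:
        return "valence"
    except Chem.KekulizeException:
        return "aromaticity"
    except Exception:
        return "sanitization"
    return "sanitization"  # parsed strictly but not under sanitize=True


def parse_and_sanitize(smiles: str, id: str = "") -> MoleculeRecord:
    """Parse and fully sanitize a SMILES string; never raises.

    Returns a valid record with the canonical SMILES, or an invalid record
    with an error category from {empty-input, syntax, unclosed-ring,
    valence, aromaticity, sanitization}.
    """
    if not smiles or not smiles.strip():
        return MoleculeRecord(id=id, smiles_input=smiles, error="empty-input")
    try:
        mol = Chem.MolFromSmiles(smiles)
    except Exception:
        mol = None
    if mol is None or mol.GetNumAtoms() == 0:
        error = "empty-input" if mol is not None else _categorize(smiles)
        return MoleculeRecord(id=id, smiles_input=smiles, error=error)
    return MoleculeRecord(
        id=id,
        smiles_input=smiles,
        smiles_canonical=Chem.MolToSmiles(mol),
        valid=True,
    )


def canonicalize(record: MoleculeRecord) -> str:
    """Canonical SMILES of a valid record (idempotent)."""
    if not record.valid:
        raise ValueError(f"cannot canonicalize invalid record {record.id!r}")
    return Chem.MolToSmiles(record.mol())


# one token per bracket atom, two-letter organic-subset element, %nn ring
# closure, or single character
_SMILES_TOKEN_RE = re.compile(r"(\[[^\]]*\]|Br|Cl|%\d{2}|.)", re.DOTALL)


def tokenize_smiles(smiles: str) -> TokenSequence:
    """Lexical tokenization of a SMILES string (no chemistry applied)."""
    return TokenSequence(
        TokenKind.SMILES, tuple(_SMILES_TOKEN_RE.findall(smiles))
    )


def encode_selfies(smiles: str) -> TokenSequence:
    """Encode a sanitizable SMILES into the robust token grammar.

    Raises :class:`selfies_grammar.EncodeError` when the molecule falls
    outside the grammar's supported chemistry.
    """
    return TokenSequence(
        TokenKind.SELFIES, tuple(selfies_grammar.encode(smiles))
    )


def decode_selfies(seq: TokenSequence | list[str]) -> str:
    """Decode tokens to SMILES; always sanitizable (or empty)."""
    tokens = list(seq.tokens) if isinstance(seq, TokenSequence) else list(seq)
    return selfies_grammar.decode(tokens)


# ---------------------------------------------------------------------------
# file I/O


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """Read a .smi file (``SMILES[TAB]id`` per line, ``#`` comments skipped).

    Lines without an explicit id get ``m{line_number}`` (1-based).
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            mol_id = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"m{lineno}"
            records.append(parse_and_sanitize(smiles, id=mol_id))
    return records


def write_smiles_file(records: list[MoleculeRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            smiles = rec.smiles_canonical if rec.valid else rec.smiles_input
            fh.write(f"{smiles}\t{rec.id}\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a headered CSV into a list of row dicts."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: missing CSV header")
        return [dict(row) for row in reader]


def write_table(rows: list[dict], path: str | Path) -> None:
    if not rows:
        Path(path).write_text("", encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
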