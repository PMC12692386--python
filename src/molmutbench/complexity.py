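"""Molecular complexity descriptors and indices.

Ten quantities are computed per molecule: five descriptors (molecular
weight MW, ring count NR, heteroatom count NH, chiral-carbon fraction QCF,
sp3-carbon fraction HCF) and five indices (Bertz BI, Hann HI, Wiener WI,
QED, Physicochemical Complexity PCI).

Two of the indices deserve a note:

* ``BI`` here is the degree-based form BI = sum_i ln(deg(i)!) over heavy
  atoms, which is *not* the classical Bertz CT implemented by RDKit; the
  classical value is available as the optional ``bertz_ct`` field for
  comparison.
* ``HI`` uses a simple structural-complexity proxy,
  (rings + heteroatoms + chiral centers) / heavy atoms, as the literature
  offers no single canonical "Hann index" formula.  It is exposed as a
  swappable function.

Parent-mutant shifts are aggregated as mean absolute differences, the
magnitude-only convention used for every conservation metric in the
benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, GraphDescriptors, rdMolDescriptors
from rdkit.Chem.QED import qed

from .chemio import MoleculeRecord

__all__ = [
    "ComplexityProfile",
    "DeltaSummary",
    "bertz_index_paper",
    "complexity_profile",
    "delta_summary",
    "hann_index",
    "pci",
    "wiener_index",
]

PROFILE_FIELDS = ("MW", "NR", "NH", "QCF", "HCF", "BI", "HI", "WI", "QED", "PCI")


@dataclass(frozen=True)
class ComplexityProfile:
    MW: float
    NR: int
    NH: int
    QCF: float
    HCF: float
    BI: float
    HI: float
    WI: float
    QED: float
    PCI: float
    bertz_ct: float | None = None  # classical Bertz CT, for comparison

    def as_dict(self) -> dict[str, float]:
        return {f: getattr(self, f) for f in PROFILE_FIELDS}


@dataclass(frozen=True)
class DeltaSummary:
    """Mean absolute parent-mutant difference per field, over valid pairs."""

    operator: str
    k: int
    mean_abs_delta: dict[str, float]
    n_pairs: int


def wiener_index(record: MoleculeRecord) -> float:
    """Half the sum of all pairwise shortest-path distances (heavy atoms).

    Raises on disconnected molecules, whose path distances are infinite.
    """
    mol = record.mol()
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError("Wiener index undefined for disconnected molecules")
    dist = Chem.GetDistanceMatrix(mol)
    return float(dist.sum() / 2.0)


def bertz_index_paper(record: MoleculeRecord) -> float:
    """Degree-based complexity: sum over heavy atoms of ln(degree!)."""
    mol = record.mol()
    return float(sum(math.lgamma(atom.GetDegree() + 1) for atom in mol.GetAtoms()))


def hann_index(record: MoleculeRecord, *, include_unassigned: bool = True) -> float:
    """Structural-complexity proxy: (rings + heteroatoms + chiral centers)
    per heavy atom; 0 for the degenerate single-atom case denominator."""
    mol = record.mol()
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy == 0:
        return 0.0
    rings = rdMolDescriptors.CalcNumRings(mol)
    hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H"))
    chiral = len(_chiral_carbons(mol, include_unassigned))
    return (rings + hetero + chiral) / n_heavy


def pci(record: MoleculeRecord, *, w_logp: float = 1.0, w_hb: float = 1.0) -> float:
    """Physicochemical complexity: w_logp * logP + w_hb * (NHA - NHD).

    logP is the Crippen fragment-contribution estimate; the octanol/water
    ratio it models is definitional, never measured here.
    """
    mol = record.mol()
    nha = rdMolDescriptors.CalcNumHBA(mol)
    nhd = rdMolDescriptors.CalcNumHBD(mol)
    return w_logp * Crippen.MolLogP(mol) + w_hb * (nha - nhd)


def _chiral_carbons(mol: Chem.Mol, include_unassigned: bool) -> list[int]:
    centers = Chem.FindMolChiralCenters(
        mol, includeUnassigned=include_unassigned, useLegacyImplementation=False
    )
    return [
        idx for idx, _ in centers if mol.GetAtomWithIdx(idx).GetSymbol() == "C"
    ]


def complexity_profile(
    record: MoleculeRecord,
    *,
    include_unassigned_stereocenters: bool = True,
    with_bertz_ct: bool = False,
) -> ComplexityProfile:
    """All ten complexity quantities for one valid molecule.

    Chiral-carbon counting includes potential (unassigned) stereocenters by
    default; fractions are 0 when the molecule has no carbons.
    """
    mol = record.mol()
    carbons = [a for a in mol.GetAtoms() if a.GetSymbol() == "C"]
    n_c = len(carbons)
    qcf = len(_chiral_carbons(mol, include_unassigned_stereocenters)) / n_c if n_c else 0.0
    return ComplexityProfile(
        MW=Descriptors.MolWt(mol),
        NR=rdMolDescriptors.CalcNumRings(mol),
        NH=sum(1 for a in mol.GetAtoms() if a.GetSymbol() not in ("C", "H")),
        QCF=qcf,
        HCF=rdMolDescriptors.CalcFractionCSP3(mol),
        BI=bertz_index_paper(record),
        HI=hann_index(record, include_unassigned=include_unassigned_stereocenters),
        WI=wiener_index(record),
        QED=qed(mol),
        PCI=pci(record),
        bertz_ct=GraphDescriptors.BertzCT(mol) if with_bertz_ct else None,
    )


def delta_summary(
    parents: list[MoleculeRecord],
    mutants: list,
    *,
    operator: str = "",
    k: int = 0,
    fields: tuple[str, ...] = PROFILE_FIELDS,
) -> DeltaSummary:
    """Mean |parent - mutant| per complexity field over valid pairs.

    ``mutants`` are MutationRecords aligned with ``parents`` by position;
    invalid mutants are excluded.  Raises when no valid pair remains.
    """
    if len(parents) != len(mutants):
        raise ValueError("parents and mutants must be aligned")
    parent_profiles: dict[str, ComplexityProfile] = {}
    sums = {f: 0.0 for f in fields}
    n = 0
    for parent, mutant in zip(parents, mutants):
        if not (parent.valid and mutant.valid):
            continue
        if parent.id not in parent_profiles:
            parent_profiles[parent.id] = complexity_profile(parent)
        from .chemio import parse_and_sanitize  # local to avoid cycle at import

        mut_rec = parse_and_sanitize(mutant.mutant_smiles, id=f"{parent.id}.mut")
        if not mut_rec.valid:
            continue
        p = parent_profiles[parent.id].as_dict()
        m = complexity_profile(mut_rec).as_dict()
        for f in fields:
            sums[f] += abs(p[f] - m[f])
        n += 1
    if n == 0:
        raise ValueError("empty-aggregate: no valid parent-mutant pairs")
    return DeltaSummary(
        operator=operator, k=k,
        mean_abs_delta={f: sums[f] / n for f in fields}, n_pairs=n,
    )
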