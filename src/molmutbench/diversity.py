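"""Structural diversity and distribution-shift analytics.

Covers four views of how a mutated population relates to its parents:
Tanimoto similarity on ECFP4 fingerprints (pairwise cumulative distribution
and parent-mutant pairs), a nine-descriptor physicochemical table,
two-component PCA on standardized descriptors, and histogram-based
Kullback-Leibler divergence between property distributions.

KL is estimated from samples with a fixed shared-range histogram (50 bins),
epsilon smoothing (1e-10 added to every bin before normalization) and the
natural log, in the direction D(original || mutated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .bioactivity import fingerprint_features, _FPGEN
from .chemio import MoleculeRecord

__all__ = [
    "DESCRIPTOR_NAMES",
    "KLEstimate",
    "PCAResult",
    "descriptor_vector",
    "fingerprint",
    "kl_divergence",
    "pairwise_similarity_cdf",
    "parent_mutant_similarity",
    "pca_fit",
    "tanimoto",
]

DESCRIPTOR_NAMES = (
    "MW", "NVE", "NRE", "TPSA", "MolLogP", "NHD", "NHA", "NRB", "FractionCSP3",
)


def fingerprint(record: MoleculeRecord):
    """ECFP4: radius-2 circular fingerprint hashed to 2048 bits."""
    return _FPGEN.GetFingerprint(record.mol())


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on fingerprint bit sets.

    Two empty fingerprints are defined as identical (1.0, with a warning).
    """
    if a.GetNumOnBits() == 0 and b.GetNumOnBits() == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 1.0")
        return 1.0
    return float(DataStructs.TanimotoSimilarity(a, b))


def pairwise_similarity_cdf(
    population: list[MoleculeRecord],
) -> list[tuple[float, float]]:
    """Empirical CDF of all n(n-1)/2 pairwise Tanimoto similarities."""
    valid = [r for r in population if r.valid]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid molecules")
    fps = [fingerprint(r) for r in valid]
    sims = sorted(
        tanimoto(fps[i], fps[j])
        for i in range(len(fps))
        for j in range(i + 1, len(fps))
    )
    n = len(sims)
    return [(s, (i + 1) / n) for i, s in enumerate(sims)]


def parent_mutant_similarity(
    pairs: list[tuple[MoleculeRecord, MoleculeRecord]],
) -> tuple[list[float], float]:
    """Tanimoto per aligned valid parent-mutant pair, plus the mean."""
    sims = [
        tanimoto(fingerprint(p), fingerprint(m))
        for p, m in pairs
        if p.valid and m.valid
    ]
    if not sims:
        raise ValueError("no valid parent-mutant pairs")
    return sims, float(np.mean(sims))


def descriptor_vector(record: MoleculeRecord) -> dict[str, float]:
    """The nine diversity descriptors (RDKit definitions).

    NRE is the unpaired-electron count, 0 for closed-shell drug-like
    molecules; TPSA is the sum of per-atom polar-surface contributions.
    """
    mol = record.mol()
    return {
        "MW": Descriptors.MolWt(mol),
        "NVE": Descriptors.NumValenceElectrons(mol),
        "NRE": Descriptors.NumRadicalElectrons(mol),
        "TPSA": rdMolDescriptors.CalcTPSA(mol),
        "MolLogP": Crippen.MolLogP(mol),
        "NHD": rdMolDescriptors.CalcNumHBD(mol),
        "NHA": rdMolDescriptors.CalcNumHBA(mol),
        "NRB": rdMolDescriptors.CalcNumRotatableBonds(mol),
        "FractionCSP3": rdMolDescriptors.CalcFractionCSP3(mol),
    }


@dataclass(frozen=True)
class PCAResult:
    columns: tuple[str, ...]
    loadings: np.ndarray  # (n_kept_descriptors, n_components)
    scores: np.ndarray  # (n_molecules, n_components)
    explained_variance_ratio: np.ndarray
    dropped_columns: tuple[str, ...] = ()


def pca_fit(table: np.ndarray | list[dict], n_components: int = 2,
            columns: tuple[str, ...] = DESCRIPTOR_NAMES) -> PCAResult:
    """PCA on standardized descriptors (zero mean, unit variance).

    Zero-variance columns are dropped with a warning.  The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    if isinstance(table, list):
        X = np.array([[row[c] for c in columns] for row in table], dtype=float)
    else:
        X = np.asarray(table, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 molecules for PCA")
    stds = X.std(axis=0)
    keep = stds > 1e-12 * (1.0 + np.abs(X).mean(axis=0))  # tolerance for fp rounding
    dropped = tuple(c for c, k in zip(columns, keep) if not k)
    if dropped:
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    X = X[:, keep]
    kept_columns = tuple(c for c, k in zip(columns, keep) if k)
    Z = StandardScaler().fit_transform(X)
    pca = PCA(n_components=min(n_components, Z.shape[1]))
    scores = pca.fit_transform(Z)
    loadings = pca.components_.T.copy()
    for comp in range(loadings.shape[1]):
        pivot = np.argmax(np.abs(loadings[:, comp]))
        if loadings[pivot, comp] < 0:
            loadings[:, comp] *= -1
            scores[:, comp] *= -1
    return PCAResult(
        columns=kept_columns,
        loadings=loadings,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        dropped_columns=dropped,
    )


@dataclass(frozen=True)
class KLEstimate:
    value: float  # nats
    n_bins: int
    epsilon: float
    support: tuple[float, float]


def kl_divergence(
    sample_p,
    sample_q,
    n_bins: int = 50,
    epsilon: float = 1e-10,
) -> KLEstimate:
    """D_KL(P || Q) = sum_x P(x) ln(P(x)/Q(x)) from histogram estimates.

    Both samples are binned over their combined min-max range; epsilon is
    added to every bin before normalization so empty Q bins stay finite.
    Identical samples give exactly 0.
    """
    p = np.asarray(sample_p, dtype=float)
    q = np.asarray(sample_q, dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("samples must be finite")
    lo = float(min(p.min(), q.min()))
    hi = float(max(p.max(), q.max()))
    if lo == hi:
        hi = lo + 1.0  # all mass in one bin either way
    edges = np.linspace(lo, hi, n_bins + 1)
    hp = np.histogram(p, bins=edges)[0].astype(float) + epsilon
    hq = np.histogram(q, bins=edges)[0].astype(float) + epsilon
    hp /= hp.sum()
    hq /= hq.sum()
    value = float(np.sum(hp * np.log(hp / hq)))
    return KLEstimate(
        value=max(value, 0.0) if np.isclose(value, 0.0) else value,
        n_bins=n_bins, epsilon=epsilon, support=(lo, hi),
    )
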