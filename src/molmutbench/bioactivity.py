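"""Conservation-of-function scoring: fingerprint QSAR and potency shifts.

A random-forest regressor maps 2048-bit radius-2 circular (ECFP4-style)
fingerprints to pIC50 (the negative log10 of the molar IC50).  Random
forests are the standard choice here: accurate on fingerprint features and
essentially tuning-free, so the model ships with library defaults (500
trees) and a fixed seed for reproducibility.

Conservation is measured as the absolute difference between the predicted
pIC50 of a parent and its mutant — magnitude only, no direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .chemio import MoleculeRecord, parse_and_sanitize

__all__ = [
    "ActivityTable",
    "PotencyShift",
    "QSARModel",
    "fingerprint_features",
    "potency_shift",
    "predict_pic50",
    "train_qsar",
]

FP_RADIUS = 2
FP_BITS = 2048

_FPGEN = rdFingerprintGenerator.GetMorganGenerator(radius=FP_RADIUS, fpSize=FP_BITS)


@dataclass(frozen=True)
class ActivityTable:
    """Rows of (smiles, pIC50); invalid SMILES are dropped at training time."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"smiles", "pIC50"} - set(self.frame.columns)
        if missing:
            raise ValueError(f"activity table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class QSARModel:
    target_id: str
    model: RandomForestRegressor
    fingerprint_spec: tuple[int, int] = (FP_RADIUS, FP_BITS)
    train_summary: dict | None = None


@dataclass(frozen=True)
class PotencyShift:
    parent_id: str
    operator: str
    pic50_parent: float
    pic50_mutant: float

    @property
    def abs_delta(self) -> float:
        return abs(self.pic50_parent - self.pic50_mutant)


def fingerprint_features(mol: Chem.Mol) -> np.ndarray:
    fp = _FPGEN.GetFingerprint(mol)
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    DataStructs.ConvertToNumpyArray(fp, arr)
    return arr


def _featurize_table(table: ActivityTable) -> tuple[np.ndarray, np.ndarray, int]:
    """Average duplicate canonical SMILES, drop unparseable rows."""
    rows: dict[str, list[float]] = {}
    dropped = 0
    for smiles, pic50 in zip(table.frame["smiles"], table.frame["pIC50"]):
        rec = parse_and_sanitize(str(smiles))
        if not rec.valid or not np.isfinite(float(pic50)):
            dropped += 1
            continue
        rows.setdefault(rec.smiles_canonical, []).append(float(pic50))
    X = np.vstack([
        fingerprint_features(Chem.MolFromSmiles(s)) for s in rows
    ]) if rows else np.empty((0, FP_BITS))
    y = np.array([float(np.mean(v)) for v in rows.values()])
    return X, y, dropped


def train_qsar(
    table: ActivityTable,
    seed: int = 0,
    *,
    target_id: str = "synthetic",
    n_estimators: int = 500,
    max_features: float | str = 0.2,
    test_fraction: float = 0.2,
    **rf_kwargs,
) -> QSARModel:
    """Fit a random-forest pIC50 regressor with a recorded held-out R^2.

    Duplicate SMILES are averaged first; unparseable rows are dropped and
    counted in the training summary.  The held-out metrics come from a
    fixed-seed 80/20 split; the deployed model is then refit on all rows,
    so identical (table, seed) inputs reproduce identical predictions.

    ``max_features=0.2`` makes each split consider a random fifth of the
    fingerprint bits — true random-forest decorrelation, which on sparse
    binary fingerprints generalizes better (and fits much faster) than
    scikit-learn's bagged-trees regression default of all features.
    """
    X, y, dropped = _featurize_table(table)
    if len(y) < 50:
        raise ValueError(f"too-few-rows: need >= 50 usable rows, got {len(y)}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed
    )
    rf = RandomForestRegressor(
        n_estimators=n_estimators, max_features=max_features,
        random_state=seed, n_jobs=1, **rf_kwargs
    )
    rf.fit(X_tr, y_tr)
    pred = rf.predict(X_te)
    summary = {
        "n": int(len(y)),
        "seed": int(seed),
        "n_dropped": int(dropped),
        "heldout_r2": float(r2_score(y_te, pred)),
        "heldout_rmse": float(np.sqrt(mean_squared_error(y_te, pred))),
    }
    final = RandomForestRegressor(
        n_estimators=n_estimators, max_features=max_features,
        random_state=seed, n_jobs=1, **rf_kwargs
    )
    final.fit(X, y)
    return QSARModel(target_id=target_id, model=final, train_summary=summary)


def predict_pic50(model: QSARModel, record: MoleculeRecord) -> float:
    """Predicted pIC50 for a valid molecule (finite; within the range of the
    training targets, a property of tree ensembles)."""
    if not record.valid:
        raise ValueError(f"cannot predict for invalid record {record.id!r}")
    features = fingerprint_features(record.mol())
    return float(model.model.predict(features.reshape(1, -1))[0])


def potency_shift(
    model: QSARModel,
    parent: MoleculeRecord,
    mutant,
    *,
    operator: str | None = None,
) -> PotencyShift:
    """Absolute predicted-potency change for one valid parent-mutant pair.

    ``mutant`` may be a MutationRecord or a MoleculeRecord.
    """
    if hasattr(mutant, "mutant_smiles"):
        mutant_rec = parse_and_sanitize(mutant.mutant_smiles, id=f"{parent.id}.mut")
        operator = operator if operator is not None else mutant.operator
    else:
        mutant_rec = mutant
    if not mutant_rec.valid:
        raise ValueError("potency shift requires a valid mutant")
    return PotencyShift(
        parent_id=parent.id,
        operator=operator or "",
        pic50_parent=predict_pic50(model, parent),
        pic50_mutant=predict_pic50(model, mutant_rec),
    )
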