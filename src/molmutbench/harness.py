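"""The benchmark protocol runner and synthetic fixture generators.

The protocol mirrors the standardized mutant-budget design: a seed
population (default 500 molecules) crossed with the five operators and
budgets k in {1, 3, 5}.  For each (operator, k) cell the harness records
validity (denominator = requested mutants, i.e. seeds x k), valid-molecule
counts, summed operator wall-clock and throughput, then computes the
conservation, complexity and diversity analytics over the valid mutants.

Because the original study's seed set (FDA-approved molecules) and
ChEMBL-trained QSAR targets are external data, the harness ships two
synthetic stand-ins that exercise the identical code paths:

* ``generate_seed_set`` draws uniform-random token sequences over the
  15-token robust alphabet and decodes them — every draw is valid by
  construction, and the resulting molecules are drug-like-sized C/N/O/F
  structures;
* ``synthetic_activity_oracle`` labels molecules with a noisy linear
  function of standardized physicochemical descriptors, clipped to the
  empirically sensible pIC50 range [2, 12].
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bioactivity import ActivityTable, QSARModel, potency_shift, predict_pic50
from .chemio import MoleculeRecord, parse_and_sanitize
from .complexity import PROFILE_FIELDS, complexity_profile
from .diversity import (
    DESCRIPTOR_NAMES,
    descriptor_vector,
    fingerprint,
    kl_divergence,
    tanimoto,
)
from .operators import (
    OPERATORS,
    EditProbabilityTable,
    MutationConfig,
    MutationRecord,
    estimate_edit_probabilities,
    generate_mutants,
    packaged_building_blocks,
    packaged_reaction_templates,
)
from . import selfies_grammar

__all__ = [
    "BenchmarkProtocol",
    "BenchmarkReport",
    "OracleParams",
    "generate_activity_dataset",
    "generate_seed_set",
    "run_benchmark",
    "synthetic_activity_oracle",
    "write_report",
]

DESCRIPTOR_DELTA_FIELDS = ("MW", "NR", "NH", "QCF", "HCF")
INDEX_DELTA_FIELDS = ("BI", "HI", "WI", "QED", "PCI")


# ---------------------------------------------------------------------------
# synthetic fixtures


def generate_seed_set(
    n: int = 500,
    min_tokens: int = 15,
    max_tokens: int = 40,
    rng_seed: int = 0,
    min_heavy_atoms: int = 10,
) -> list[MoleculeRecord]:
    """``n`` distinct valid molecules from random robust-grammar strings.

    Token lengths are uniform on [min_tokens, max_tokens]; the grammar
    guarantees validity, and duplicates (by canonical SMILES), empty
    decodes and undersized molecules are resampled.  Random derivations
    often terminate early at saturated atoms, so without a size floor the
    population would be dominated by fragments of a few atoms; the
    ``min_heavy_atoms`` filter (default 10) keeps the seeds in the
    small-drug size range the mutant-budget protocol presumes.
    Deterministic under ``rng_seed``.
    """
    if n < 1 or not (1 <= min_tokens <= max_tokens):
        raise ValueError("need n >= 1 and 1 <= min_tokens <= max_tokens")
    rng = np.random.default_rng(rng_seed)
    alphabet = selfies_grammar.ALPHABET
    seen: set[str] = set()
    records: list[MoleculeRecord] = []
    for _ in range(100 * n):
        if len(records) == n:
            break
        length = int(rng.integers(min_tokens, max_tokens + 1))
        tokens = [alphabet[int(i)] for i in rng.integers(0, len(alphabet), length)]
        smiles = selfies_grammar.decode(tokens)
        if not smiles or smiles in seen:
            continue
        rec = parse_and_sanitize(smiles, id=f"seed{len(records) + 1}")
        if rec.mol().GetNumHeavyAtoms() < min_heavy_atoms:
            continue
        seen.add(smiles)
        records.append(rec)
    if len(records) < n:
        raise RuntimeError(f"could not reach {n} distinct molecules in {100 * n} draws")
    return records


@dataclass(frozen=True)
class OracleParams:
    """Linear structure-activity ground truth over the nine descriptors.

    Reference means/scales standardize the descriptors onto comparable
    axes.  The weights place the signal on pharmacophore-style features —
    hydrogen-bond donors/acceptors, polarity, lipophilicity, saturation and
    flexibility — the substructure-determined properties that drive
    target binding and that a circular-fingerprint QSAR is built to see;
    raw mass and electron counts carry no independent signal.  The
    resulting spread is ~1-1.5 pIC50 units over the synthetic population.
    """

    weights: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0, 0.4, 0.9, 0.0, 0.0, 0.9)
    feature_means: tuple[float, ...] = (160.0, 60.0, 0.0, 60.0, 0.0, 2.0, 4.0, 4.0, 0.5)
    feature_scales: tuple[float, ...] = (60.0, 25.0, 1.0, 35.0, 1.5, 1.5, 2.0, 3.0, 0.3)
    intercept: float = 6.5
    noise_sigma: float = 0.3
    clip: tuple[float, float] = (2.0, 12.0)

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def synthetic_activity_oracle(
    record: MoleculeRecord,
    params: OracleParams,
    rng: np.random.Generator | None = None,
) -> float:
    """Ground-truth pIC50: clip(intercept + w . z(descriptors) + noise)."""
    desc = descriptor_vector(record)
    x = np.array([desc[name] for name in DESCRIPTOR_NAMES])
    z = (x - np.asarray(params.feature_means)) / np.asarray(params.feature_scales)
    value = params.intercept + float(np.dot(params.weights, z))
    if params.noise_sigma > 0:
        if rng is None:
            raise ValueError("rng required when noise_sigma > 0")
        value += float(rng.normal(0.0, params.noise_sigma))
    return float(np.clip(value, *params.clip))


def generate_activity_dataset(
    n: int,
    params: OracleParams | None = None,
    rng_seed: int = 0,
) -> ActivityTable:
    """``n`` oracle-labeled synthetic molecules as an activity table."""
    if n < 50:
        raise ValueError("need n >= 50")
    params = params or OracleParams()
    seeds = generate_seed_set(n, rng_seed=rng_seed)
    rng = np.random.default_rng(rng_seed + 1)
    rows = [
        {"smiles": rec.smiles_canonical,
         "pIC50": synthetic_activity_oracle(rec, params, rng)}
        for rec in seeds
    ]
    return ActivityTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# protocol


@dataclass
class BenchmarkProtocol:
    seeds: list[MoleculeRecord]
    operators: tuple[str, ...] = OPERATORS
    budgets: tuple[int, ...] = (1, 3, 5)
    rng_seed: int = 0
    configs: dict[str, MutationConfig] = field(default_factory=dict)
    qsar_models: dict[str, QSARModel] = field(default_factory=dict)
    gbgm_corpus: list[MoleculeRecord] | None = None  # defaults to the seeds

    def __post_init__(self) -> None:
        if any(not s.valid for s in self.seeds):
            raise ValueError("all protocol seeds must be valid")
        if any(k < 1 for k in self.budgets):
            raise ValueError("budgets must be positive")
        unknown = set(self.operators) - set(OPERATORS)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")

    def config_for(self, operator: str) -> MutationConfig:
        if operator in self.configs:
            return self.configs[operator]
        cap = 50 if operator in ("GB-GA", "GB-GM") else 0
        return MutationConfig(operator=operator, resample_cap=cap,
                              rng_seed=self.rng_seed)


@dataclass
class BenchmarkReport:
    """Aggregate tables of one benchmark run (pandas DataFrames)."""

    summary: pd.DataFrame  # per (operator, k): validity, molecules, time, mol/s
    complexity_deltas: pd.DataFrame  # per (operator, k, field): mean |delta|
    potency_shifts: pd.DataFrame  # per (operator, k, target): mean |delta pIC50|
    kl_descriptors: pd.DataFrame  # per (operator, descriptor): KL nats
    kl_potency: pd.DataFrame  # per (operator, target): KL nats
    similarity: pd.DataFrame  # per (operator, k): mean parent-mutant Tanimoto
    ranks: pd.DataFrame  # per aspect: operator ordering by mean |delta|
    config: dict = field(default_factory=dict)
    mutation_records: dict = field(default_factory=dict)  # (operator, k) -> list


def _mutant_record(parent: MoleculeRecord, mut: MutationRecord) -> MoleculeRecord | None:
    if not mut.valid:
        return None
    rec = parse_and_sanitize(mut.mutant_smiles, id=f"{parent.id}.mut")
    return rec if rec.valid else None


def run_benchmark(
    protocol: BenchmarkProtocol,
    operator_fns: dict | None = None,
) -> BenchmarkReport:
    """Execute the full protocol and aggregate every report table.

    ``operator_fns`` optionally overrides an operator with a callable
    ``fn(record, cfg, k, rng) -> list[MutationRecord]`` — used for
    bookkeeping tests with scripted populations.  Per-molecule failures are
    recorded as invalid mutants, never fatal.
    """
    operator_fns = operator_fns or {}
    seeds = protocol.seeds
    needs_gbgm = "GB-GM" in protocol.operators and "GB-GM" not in operator_fns
    table: EditProbabilityTable | None = None
    if needs_gbgm:
        table = estimate_edit_probabilities(protocol.gbgm_corpus or seeds)
    needs_scc = "SCC" in protocol.operators and "SCC" not in operator_fns
    templates = packaged_reaction_templates() if needs_scc else None
    library = packaged_building_blocks() if needs_scc else None

    records: dict[tuple[str, int], list[list[MutationRecord]]] = {}
    summary_rows = []
    for op_i, operator in enumerate(protocol.operators):
        cfg = protocol.config_for(operator)
        for k_i, k in enumerate(protocol.budgets):
            cell: list[list[MutationRecord]] = []
            elapsed = 0.0
            for seed_i, seed in enumerate(seeds):
                rng = np.random.default_rng(np.random.SeedSequence(
                    entropy=protocol.rng_seed, spawn_key=(op_i, k_i, seed_i)))
                if operator in operator_fns:
                    muts = operator_fns[operator](seed, cfg, k, rng)
                else:
                    kwargs = {}
                    if operator == "GB-GM":
                        kwargs["table"] = table
                    if operator == "SCC":
                        kwargs["templates"] = templates
                        kwargs["library"] = library
                    muts = generate_mutants(seed, cfg, k, rng, **kwargs)
                cell.append(muts)
                elapsed += sum(m.elapsed_s for m in muts)
            records[(operator, k)] = cell
            n_valid = sum(m.valid for muts in cell for m in muts)
            requested = len(seeds) * k
            summary_rows.append({
                "operator": operator,
                "k": k,
                "validity_percent": 100.0 * n_valid / requested,
                "molecules": n_valid,
                "time_s": elapsed,
                "mol_per_s": n_valid / elapsed if elapsed > 0 else float("nan"),
            })
    summary = pd.DataFrame(summary_rows)

    # cached parent/mutant property computations
    parent_profiles = {s.id: complexity_profile(s).as_dict() for s in seeds}
    parent_desc = {s.id: descriptor_vector(s) for s in seeds}
    parent_fp = {s.id: fingerprint(s) for s in seeds}
    parent_pic50 = {
        target: {s.id: predict_pic50(model, s) for s in seeds}
        for target, model in protocol.qsar_models.items()
    }

    delta_rows, shift_rows, sim_rows = [], [], []
    pooled_desc: dict[str, dict[str, list[float]]] = {}
    pooled_pic50: dict[str, dict[str, list[float]]] = {}
    for (operator, k), cell in records.items():
        sums = {f: 0.0 for f in PROFILE_FIELDS}
        n_pairs = 0
        sims = []
        shift_sums = {t: 0.0 for t in protocol.qsar_models}
        shift_ns = {t: 0 for t in protocol.qsar_models}
        for seed, muts in zip(seeds, cell):
            for mut in muts:
                mrec = _mutant_record(seed, mut)
                if mrec is None:
                    continue
                mprof = complexity_profile(mrec).as_dict()
                for f in PROFILE_FIELDS:
                    sums[f] += abs(parent_profiles[seed.id][f] - mprof[f])
                n_pairs += 1
                sims.append(tanimoto(parent_fp[seed.id], fingerprint(mrec)))
                mdesc = descriptor_vector(mrec)
                bucket = pooled_desc.setdefault(operator, {d: [] for d in DESCRIPTOR_NAMES})
                for d in DESCRIPTOR_NAMES:
                    bucket[d].append(mdesc[d])
                for target, model in protocol.qsar_models.items():
                    pred = predict_pic50(model, mrec)
                    shift_sums[target] += abs(parent_pic50[target][seed.id] - pred)
                    shift_ns[target] += 1
                    pooled_pic50.setdefault(operator, {t: [] for t in protocol.qsar_models})
                    pooled_pic50[operator][target].append(pred)
        for f in PROFILE_FIELDS:
            delta_rows.append({
                "operator": operator, "k": k, "field": f,
                "mean_abs_delta": sums[f] / n_pairs if n_pairs else float("nan"),
                "n_pairs": n_pairs,
            })
        sim_rows.append({
            "operator": operator, "k": k,
            "mean_tanimoto": float(np.mean(sims)) if sims else float("nan"),
            "n_pairs": len(sims),
        })
        for target in protocol.qsar_models:
            shift_rows.append({
                "operator": operator, "k": k, "target": target,
                "mean_abs_delta_pic50": (
                    shift_sums[target] / shift_ns[target]
                    if shift_ns[target] else float("nan")
                ),
                "n_pairs": shift_ns[target],
            })

    kl_desc_rows = []
    original_desc = {d: [parent_desc[s.id][d] for s in seeds] for d in DESCRIPTOR_NAMES}
    for operator in protocol.operators:
        for d in DESCRIPTOR_NAMES:
            pooled = pooled_desc.get(operator, {}).get(d, [])
            kl_desc_rows.append({
                "operator": operator, "descriptor": d,
                "kl_nats": (
                    kl_divergence(original_desc[d], pooled).value
                    if pooled else float("nan")
                ),
            })
    kl_pot_rows = []
    for operator in protocol.operators:
        for target in protocol.qsar_models:
            pooled = pooled_pic50.get(operator, {}).get(target, [])
            originals = list(parent_pic50[target].values())
            kl_pot_rows.append({
                "operator": operator, "target": target,
                "kl_nats": (
                    kl_divergence(originals, pooled).value
                    if pooled else float("nan")
                ),
            })

    deltas = pd.DataFrame(delta_rows)
    similarity = pd.DataFrame(sim_rows)
    shifts = pd.DataFrame(shift_rows) if shift_rows else pd.DataFrame(
        columns=["operator", "k", "target", "mean_abs_delta_pic50", "n_pairs"])
    ranks = _rank_table(summary, deltas, shifts, similarity, protocol)
    return BenchmarkReport(
        summary=summary,
        complexity_deltas=deltas,
        potency_shifts=shifts,
        kl_descriptors=pd.DataFrame(kl_desc_rows),
        kl_potency=pd.DataFrame(kl_pot_rows) if kl_pot_rows else pd.DataFrame(
            columns=["operator", "target", "kl_nats"]),
        similarity=similarity,
        ranks=ranks,
        config={
            "rng_seed": protocol.rng_seed,
            "n_seeds": len(seeds),
            "budgets": list(protocol.budgets),
            "operators": list(protocol.operators),
            "seed_smiles": [s.smiles_canonical for s in seeds],
        },
        mutation_records={key: cell for key, cell in records.items()},
    )


def _rank_table(summary, deltas, shifts, similarity, protocol) -> pd.DataFrame:
    """Per-aspect operator ordering (1 = largest effect / best metric)."""
    rows = []
    by_op = summary.groupby("operator", sort=False)
    aspects: dict[str, pd.Series] = {
        # higher validity and higher throughput rank first
        "validity": by_op["validity_percent"].mean().sort_values(ascending=False),
        "speed": by_op["mol_per_s"].mean().sort_values(ascending=False),
    }
    desc_mask = deltas["field"].isin(DESCRIPTOR_DELTA_FIELDS)
    idx_mask = deltas["field"].isin(INDEX_DELTA_FIELDS)
    # mean |delta| normalized per field so fields on different scales
    # contribute equally to the ordering
    for name, mask in (("complexity_descriptors", desc_mask),
                       ("complexity_indices", idx_mask)):
        sub = deltas[mask].copy()
        sub["scaled"] = sub.groupby("field")["mean_abs_delta"].transform(
            lambda s: s / s.max() if s.max() > 0 else s)
        aspects[name] = (
            sub.groupby("operator", sort=False)["scaled"].mean()
            .sort_values(ascending=False)
        )
    if not shifts.empty:
        aspects["pic50_shift"] = (
            shifts.groupby("operator", sort=False)["mean_abs_delta_pic50"]
            .mean().sort_values(ascending=False)
        )
    # diversity: lower parent-mutant similarity = more diverse = rank 1
    aspects["diversity"] = (
        similarity.groupby("operator", sort=False)["mean_tanimoto"]
        .mean().sort_values(ascending=True)
    )
    for aspect, ordered in aspects.items():
        for rank, (operator, value) in enumerate(ordered.items(), start=1):
            rows.append({"aspect": aspect, "rank": rank,
                         "operator": operator, "value": float(value)})
    return pd.DataFrame(rows)


def write_report(report: BenchmarkReport, outdir: str | Path) -> list[Path]:
    """Write the report tables as CSVs plus a replayable run_config.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    tables = {
        "summary.csv": report.summary,
        "complexity_deltas.csv": report.complexity_deltas,
        "potency_shifts.csv": report.potency_shifts,
        "kl_descriptors.csv": report.kl_descriptors,
        "kl_potency.csv": report.kl_potency,
        "similarity.csv": report.similarity,
        "ranks.csv": report.ranks,
    }
    for name, frame in tables.items():
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)
    config_path = outdir / "run_config.json"
    config_path.write_text(json.dumps(report.config, indent=2), encoding="utf-8")
    written.append(config_path)
    return written
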