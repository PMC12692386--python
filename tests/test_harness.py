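"""Protocol runner bookkeeping, synthetic generators and report output."""

import json

import numpy as np
import pandas as pd
import pytest

import molmutbench as mmb
from molmutbench.chemio import parse_and_sanitize
from molmutbench.harness import (
    BenchmarkProtocol,
    OracleParams,
    generate_activity_dataset,
    generate_seed_set,
    run_benchmark,
    synthetic_activity_oracle,
    write_report,
)
from molmutbench.operators import MutationRecord


class TestGenerateSeedSet:
    def test_distinct_valid_and_deterministic(self):
        a = generate_seed_set(40, rng_seed=9)
        b = generate_seed_set(40, rng_seed=9)
        assert [r.smiles_canonical for r in a] == [r.smiles_canonical for r in b]
        assert len({r.smiles_canonical for r in a}) == 40
        assert all(r.valid for r in a)

    def test_alphabet_closure(self, seed_set):
        for rec in seed_set:
            symbols = {a.GetSymbol() for a in rec.mol().GetAtoms()}
            assert symbols <= {"C", "N", "O", "F"}

    def test_size_floor_respected(self, seed_set):
        assert all(r.mol().GetNumHeavyAtoms() >= 10 for r in seed_set)

    def test_bad_arguments_rejected(self):
        with pytest.raises(ValueError):
            generate_seed_set(0)
        with pytest.raises(ValueError):
            generate_seed_set(5, min_tokens=10, max_tokens=5)


class TestSyntheticOracle:
    def test_noiseless_is_repeatable_and_descriptor_determined(self, seed_set):
        params = OracleParams(noise_sigma=0.0)
        a = [synthetic_activity_oracle(r, params) for r in seed_set[:10]]
        b = [synthetic_activity_oracle(r, params) for r in seed_set[:10]]
        assert a == b

    def test_output_clipped(self, seed_set):
        params = OracleParams(noise_sigma=5.0)
        rng = np.random.default_rng(0)
        for rec in seed_set:
            v = synthetic_activity_oracle(rec, params, rng)
            assert 2.0 <= v <= 12.0

    def test_dataset_boundary_and_determinism(self):
        t1 = generate_activity_dataset(50, rng_seed=4)
        t2 = generate_activity_dataset(50, rng_seed=4)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)
        with pytest.raises(ValueError):
            generate_activity_dataset(49)


def _scripted_operator(n_valid_per_k, total_time):
    """Mocked operator: emits exactly ``n_valid_per_k[k]`` valid mutants over
    the whole population, each record carrying an equal share of
    ``total_time`` seconds."""
    state = {"emitted": 0}

    def fn(record, cfg, k, rng):
        out = []
        for _ in range(k):
            valid = state["emitted"] < n_valid_per_k
            state["emitted"] += 1
            out.append(MutationRecord(
                parent_id=record.id, operator=cfg.operator,
                mutant_smiles="CCO" if valid else "C1CC",
                valid=valid, elapsed_s=total_time / state["total"],
                attempts=1))
        return out

    def bind_total(total):
        state["total"] = total
        return fn

    return bind_total


class TestRunBenchmarkBookkeeping:
    @pytest.mark.parametrize("n_seeds,k,n_valid,total_time,expect_pct", [
        (500, 1, 486, 145.2, 97.2),   # 486/500
        (500, 3, 1446, 142.4, 96.4),  # 1446/1500
        (500, 3, 448, 1.986e-2, 29.9),  # 448/1500
    ])
    def test_scripted_population_arithmetic(self, seed_set_500, n_seeds, k,
                                            n_valid, total_time, expect_pct):
        seeds = seed_set_500[:n_seeds]
        protocol = BenchmarkProtocol(
            seeds=seeds, operators=("SM-T",), budgets=(k,), rng_seed=0)
        op = _scripted_operator(n_valid, total_time)(n_seeds * k)
        report = run_benchmark(protocol, operator_fns={"SM-T": op})
        row = report.summary.iloc[0]
        assert row["molecules"] == n_valid
        assert row["validity_percent"] == pytest.approx(expect_pct, abs=0.05)
        assert row["time_s"] == pytest.approx(total_time, rel=1e-9)
        assert row["mol_per_s"] == pytest.approx(
            n_valid / total_time, rel=1e-9)

    def test_all_valid_scripted_operator(self, seed_set):
        protocol = BenchmarkProtocol(
            seeds=seed_set, operators=("SM-T",), budgets=(1,), rng_seed=0)
        op = _scripted_operator(len(seed_set), 1.0)(len(seed_set))
        report = run_benchmark(protocol, operator_fns={"SM-T": op})
        assert report.summary.iloc[0]["validity_percent"] == 100.0

    def test_bookkeeping_identities_on_real_run(self, seed_set):
        protocol = BenchmarkProtocol(
            seeds=seed_set, operators=("SM-T", "SF-T"), budgets=(1, 3),
            rng_seed=5)
        report = run_benchmark(protocol)
        for _, row in report.summary.iterrows():
            n_req = len(seed_set) * row["k"]
            assert row["validity_percent"] == pytest.approx(
                100.0 * row["molecules"] / n_req, rel=1e-12)
            assert row["mol_per_s"] * row["time_s"] == pytest.approx(
                row["molecules"], abs=1e-9)

    def test_all_sections_present(self, seed_set):
        protocol = BenchmarkProtocol(
            seeds=seed_set, operators=("SF-T",), budgets=(1,), rng_seed=2)
        report = run_benchmark(protocol)
        assert not report.summary.empty
        assert not report.complexity_deltas.empty
        assert not report.kl_descriptors.empty
        assert not report.similarity.empty
        assert not report.ranks.empty
        assert report.potency_shifts.empty  # no QSAR model supplied


class TestWriteReport:
    def test_round_trip_summary(self, tmp_path, seed_set):
        protocol = BenchmarkProtocol(
            seeds=seed_set, operators=("SM-T",), budgets=(1,), rng_seed=3)
        report = run_benchmark(protocol)
        write_report(report, tmp_path)
        back = pd.read_csv(tmp_path / "summary.csv")
        pd.testing.assert_frame_equal(back, report.summary)
        config = json.loads((tmp_path / "run_config.json").read_text())
        assert config["rng_seed"] == 3
        assert len(config["seed_smiles"]) == len(seed_set)

    def test_ranks_are_complete_orderings(self, tmp_path, seed_set):
        protocol = BenchmarkProtocol(
            seeds=seed_set, operators=("SM-T", "SF-T", "GB-GA"),
            budgets=(1,), rng_seed=3)
        report = run_benchmark(protocol)
        for aspect, group in report.ranks.groupby("aspect"):
            assert sorted(group["rank"]) == [1, 2, 3]
            assert set(group["operator"]) == {"SM-T", "SF-T", "GB-GA"}

    def test_replay_reproduces_report(self, tmp_path, seed_set):
        """run_config.json + same seed reproduce every table bit-for-bit
        (timing-derived columns excluded)."""
        protocol = BenchmarkProtocol(
            seeds=seed_set[:20], operators=("SF-T", "SM-T"), budgets=(1, 3),
            rng_seed=11)
        first = run_benchmark(protocol)
        write_report(first, tmp_path)
        config = json.loads((tmp_path / "run_config.json").read_text())
        seeds2 = [parse_and_sanitize(s, f"seed{i+1}")
                  for i, s in enumerate(config["seed_smiles"])]
        second = run_benchmark(BenchmarkProtocol(
            seeds=seeds2, operators=tuple(config["operators"]),
            budgets=tuple(config["budgets"]), rng_seed=config["rng_seed"]))
        drop = ["time_s", "mol_per_s"]
        pd.testing.assert_frame_equal(
            first.summary.drop(columns=drop), second.summary.drop(columns=drop))
        pd.testing.assert_frame_equal(
            first.complexity_deltas, second.complexity_deltas)
        pd.testing.assert_frame_equal(first.similarity, second.similarity)
        pd.testing.assert_frame_equal(
            first.kl_descriptors, second.kl_descriptors)
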