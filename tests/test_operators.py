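"""Mechanics, guarantees and statistics of the five mutation operators."""

import numpy as np
import pytest
from scipy import stats

import molmutbench as mmb
from molmutbench.chemio import (
    SELFIES_ALPHABET,
    SMILES_ALPHABET,
    TokenKind,
    TokenSequence,
    parse_and_sanitize,
)
from molmutbench.operators import (
    MutationConfig,
    estimate_edit_probabilities,
    generate_mutants,
    graph_generative_mutation,
    graph_mutation_gbga,
    mutate_token_sequence,
    packaged_building_blocks,
    packaged_reaction_templates,
    reaction_mutation,
    selfies_token_mutation,
    smiles_token_mutation,
)
from rdkit import Chem
from rdkit.Chem import Descriptors


def _molwt(smiles):
    return Descriptors.MolWt(Chem.MolFromSmiles(smiles))


class TestMutateTokenSequence:
    def test_single_edit_changes_length_by_at_most_one(self, rng):
        seq = TokenSequence(TokenKind.SMILES, tuple("CCOCC"))
        for _ in range(50):
            out, trace = mutate_token_sequence(seq, SMILES_ALPHABET, rng)
            assert abs(len(out) - len(seq)) <= 1
            assert trace.split()[0] in ("insert", "replace", "delete")

    def test_replace_never_reproduces_symbol(self, rng):
        seq = TokenSequence(TokenKind.SMILES, ("C",))
        for _ in range(200):
            out, trace = mutate_token_sequence(seq, SMILES_ALPHABET, rng)
            if trace.startswith("replace"):
                assert out.tokens[0] != "C"

    def test_delete_to_empty_allowed(self, rng):
        seq = TokenSequence(TokenKind.SMILES, ("C",))
        seen_empty = False
        for _ in range(50):
            out, trace = mutate_token_sequence(seq, SMILES_ALPHABET, rng)
            if trace.startswith("delete"):
                assert len(out) == 0
                seen_empty = True
        assert seen_empty

    def test_edit_on_empty_sequence_raises(self, rng):
        empty = TokenSequence(TokenKind.SMILES, ())
        with pytest.raises(ValueError):
            for _ in range(20):  # kind is random; hit replace/delete
                mutate_token_sequence(empty, SMILES_ALPHABET, rng)

    def test_edit_kinds_uniform(self):
        """Over 10,000 edits each kind appears with frequency 1/3 +- 0.02."""
        rng = np.random.default_rng(99)
        seq = TokenSequence(TokenKind.SMILES, tuple("CCOCCN"))
        counts = {"insert": 0, "replace": 0, "delete": 0}
        for _ in range(10_000):
            _, trace = mutate_token_sequence(seq, SMILES_ALPHABET, rng)
            counts[trace.split()[0]] += 1
        for kind, c in counts.items():
            assert abs(c / 10_000 - 1 / 3) < 0.02, kind
        chi2 = stats.chisquare(list(counts.values())).statistic
        assert chi2 < 16.27  # p > 0.0003 for 2 dof


class TestSmilesTokenMutation:
    def test_mechanics_examples(self, rng):
        parent = parse_and_sanitize("CCO", "p")
        cfg = MutationConfig(operator="SM-T")
        outcomes = {mmb.smiles_token_mutation(parent, cfg, rng).mutant_smiles
                    for _ in range(300)}
        assert "CCN" in outcomes  # replace O -> N
        invalid_ring = [
            r for r in (smiles_token_mutation(parent, cfg, rng) for _ in range(300))
            if not r.valid and r.error == "unclosed-ring"
        ]
        assert invalid_ring  # inserting a lone ring digit breaks closure

    def test_validity_below_sft_on_shared_parents(self, seed_set):
        rng = np.random.default_rng(3)
        cfg_smt = MutationConfig(operator="SM-T")
        cfg_sft = MutationConfig(operator="SF-T")
        smt = [smiles_token_mutation(s, cfg_smt, rng) for s in seed_set]
        sft = [selfies_token_mutation(s, cfg_sft, rng) for s in seed_set]
        v_smt = np.mean([r.valid for r in smt])
        v_sft = np.mean([r.valid for r in sft])
        assert v_smt < v_sft


class TestSelfiesTokenMutation:
    def test_nonempty_mutants_always_valid(self, seed_set):
        rng = np.random.default_rng(8)
        cfg = MutationConfig(operator="SF-T")
        for seed in seed_set[:20]:
            for _ in range(25):
                rec = selfies_token_mutation(seed, cfg, rng)
                if rec.mutant_smiles:
                    assert rec.valid
                else:
                    assert not rec.valid

    def test_replace_usually_changes_molecule(self):
        rng = np.random.default_rng(17)
        parent = parse_and_sanitize("CC(Cc1ccc2c(c1)OCO2)NC", "mdma")
        cfg = MutationConfig(operator="SF-T")
        changed = total = 0
        for _ in range(400):
            rec = selfies_token_mutation(parent, cfg, rng)
            if rec.edit_trace and rec.edit_trace[0].startswith("replace") and rec.valid:
                total += 1
                changed += rec.mutant_smiles != parent.smiles_canonical
        assert total > 50
        assert changed / total >= 0.95


class TestGraphMutationGBGA:
    def test_remove_atom_can_give_ethane(self, rng):
        parent = parse_and_sanitize("CCO", "p")
        cfg = MutationConfig(operator="GB-GA", resample_cap=50)
        outcomes = {graph_mutation_gbga(parent, cfg, rng).mutant_smiles
                    for _ in range(200)}
        assert "CC" in outcomes

    def test_emitted_validity_with_resampling(self, seed_set):
        rng = np.random.default_rng(21)
        cfg = MutationConfig(operator="GB-GA", resample_cap=50)
        records = [graph_mutation_gbga(s, cfg, rng) for s in seed_set]
        assert np.mean([r.valid for r in records]) >= 0.99

    def test_valid_flag_matches_external_check(self, seed_set, rng):
        cfg = MutationConfig(operator="GB-GA", resample_cap=10)
        for seed in seed_set[:20]:
            rec = graph_mutation_gbga(seed, cfg, rng)
            assert rec.valid == parse_and_sanitize(rec.mutant_smiles).valid

    def test_determinism_under_fixed_seed(self, seed_set):
        cfg = MutationConfig(operator="GB-GA", resample_cap=50)
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            runs.append([graph_mutation_gbga(s, cfg, rng).mutant_smiles
                         for s in seed_set[:15]])
        assert runs[0] == runs[1]


class TestEditProbabilities:
    def test_single_bond_corpus(self):
        table = estimate_edit_probabilities([parse_and_sanitize("CC", "a")])
        assert table.attach["C"][("C", 1)] == pytest.approx(1.0)

    def test_hydrocarbon_corpus_has_no_heteroatom_support(self):
        corpus = [parse_and_sanitize(s, str(i))
                  for i, s in enumerate(["CCC", "C1CCCCC1", "CC=CC"])]
        table = estimate_edit_probabilities(corpus)
        events = {e for ctx in table.attach.values() for e, _ in ctx.items()}
        assert all(elem == "C" for elem, _ in events)

    def test_normalization_per_context(self, random_molecules):
        table = estimate_edit_probabilities(random_molecules)
        for ctx, events in table.attach.items():
            assert sum(events.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(table.kind.values()) == pytest.approx(1.0, abs=1e-9)

    def test_order_invariance(self, random_molecules):
        fwd = estimate_edit_probabilities(random_molecules)
        rev = estimate_edit_probabilities(list(reversed(random_molecules)))
        assert fwd == rev

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            estimate_edit_probabilities([])


class TestGraphGenerativeMutation:
    def test_support_closure_on_hydrocarbon_table(self, rng):
        corpus = [parse_and_sanitize(s, str(i))
                  for i, s in enumerate(["CCC", "CCCC", "C1CCCCC1"])]
        table = estimate_edit_probabilities(corpus)
        parent = parse_and_sanitize("CCO", "p")
        cfg = MutationConfig(operator="GB-GM", resample_cap=50)
        for _ in range(30):
            rec = graph_generative_mutation(parent, table, cfg, rng)
            if rec.valid:
                added = Chem.MolFromSmiles(rec.mutant_smiles)
                # parent had 1 O; growth may only add carbons
                n_o = sum(1 for a in added.GetAtoms() if a.GetSymbol() == "O")
                assert n_o == 1

    def test_growth_bias(self, seed_set, rng):
        table = estimate_edit_probabilities(seed_set)
        cfg = MutationConfig(operator="GB-GM", resample_cap=50)
        grew = total = 0
        for seed in seed_set[:40]:
            n_parent = seed.mol().GetNumHeavyAtoms()
            rec = graph_generative_mutation(seed, table, cfg, rng)
            if rec.valid:
                total += 1
                grew += (Chem.MolFromSmiles(rec.mutant_smiles).GetNumHeavyAtoms()
                         >= n_parent)
        assert total > 30
        assert grew / total >= 0.9

    def test_determinism(self, seed_set):
        table = estimate_edit_probabilities(seed_set)
        cfg = MutationConfig(operator="GB-GM", resample_cap=50)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(55)
            out.append([graph_generative_mutation(s, table, cfg, rng).mutant_smiles
                        for s in seed_set[:15]])
        assert out[0] == out[1]


class TestReactionMutation:
    def test_amide_coupling_mass_balance(self, rng):
        templates = [t for t in packaged_reaction_templates()
                     if t.name == "amide_coupling"]
        library = packaged_building_blocks()
        parent = parse_and_sanitize("CCCC(=O)O", "acid")
        cfg = MutationConfig(operator="SCC")
        rec = reaction_mutation(parent, templates, library, cfg, rng)
        assert rec.valid
        assert Chem.MolFromSmiles(rec.mutant_smiles).HasSubstructMatch(
            Chem.MolFromSmarts("C(=O)N"))
        reagent = rec.edit_trace[0].split("reagent ")[1]
        expected = _molwt(parent.smiles_canonical) + _molwt(reagent) - 18.02
        assert _molwt(rec.mutant_smiles) == pytest.approx(expected, abs=0.01)

    def test_no_template_match(self, rng):
        templates = packaged_reaction_templates()
        library = packaged_building_blocks()
        parent = parse_and_sanitize("C1CCCCC1", "cyclohexane")
        cfg = MutationConfig(operator="SCC")
        rec = reaction_mutation(parent, templates, library, cfg, rng)
        assert not rec.valid
        assert rec.error == "no-template-match"

    def test_mean_mw_shift_positive(self, seed_set, rng):
        templates = packaged_reaction_templates()
        library = packaged_building_blocks()
        cfg = MutationConfig(operator="SCC")
        deltas = []
        for seed in seed_set:
            rec = reaction_mutation(seed, templates, library, cfg, rng)
            if rec.valid:
                deltas.append(_molwt(rec.mutant_smiles)
                              - _molwt(seed.smiles_canonical))
        assert len(deltas) > 10
        assert np.mean(deltas) > 0


class TestGenerateMutants:
    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_exactly_k_records(self, seed_set, rng, k):
        cfg = MutationConfig(operator="SM-T")
        records = generate_mutants(seed_set[0], cfg, k, rng)
        assert len(records) == k
        assert all(r.parent_id == seed_set[0].id for r in records)

    def test_identical_seed_identical_mutants(self, seed_set):
        cfg = MutationConfig(operator="SF-T")
        a = generate_mutants(seed_set[0], cfg, 5, np.random.default_rng(4))
        b = generate_mutants(seed_set[0], cfg, 5, np.random.default_rng(4))
        assert [r.mutant_smiles for r in a] == [r.mutant_smiles for r in b]

    def test_validity_denominator_is_requested_count(self, seed_set):
        cfg = MutationConfig(operator="SM-T")
        rng = np.random.default_rng(10)
        records = [r for s in seed_set for r in generate_mutants(s, cfg, 3, rng)]
        assert len(records) == len(seed_set) * 3
        validity = sum(r.valid for r in records) / len(records)
        assert 0.0 <= validity <= 1.0
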