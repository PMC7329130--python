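"""Data model, energies, counting, projection and JSON round trips."""

import json
import math

import pytest

from kstardesign.confspace import (
    Constants,
    DesignPosition,
    EnergyMatrix,
    MinimizedEnergyModel,
    ResidueType,
    SchemaError,
    Sequence,
    ValidationError,
    conf_count,
    dumps_problem,
    loads_problem,
    lower_bound_energy,
    project_sequence,
)
from kstardesign.synthgen import GeneratorParams, generate_problem

from _brute import all_state_sequences, brute_conformations
from conftest import small_problem

X = Sequence.from_dict({0: "X"})
Y = Sequence.from_dict({0: "Y"})


class TestTypesAndInvariants:
    def test_residue_type_rejects_empty_and_duplicate_rotamers(self):
        with pytest.raises(ValidationError):
            ResidueType("A", ())
        with pytest.raises(ValidationError):
            ResidueType("A", ("r1", "r1"))

    def test_wild_type_must_be_allowed(self):
        t = ResidueType("A", ("r1",))
        with pytest.raises(ValidationError):
            DesignPosition(index=0, label="p", allowed_types=(t,), wild_type="B")

    def test_mutability_derived_from_type_count(self):
        a, b = ResidueType("A", ("r1",)), ResidueType("B", ("r1",))
        assert not DesignPosition(0, "p", (a,), "A").mutable
        assert DesignPosition(0, "p", (a, b), "A").mutable

    def test_pair_energy_symmetric_storage(self):
        em = EnergyMatrix()
        em.set_pair(1, "B", "r1", 0, "A", "r1", 2.5)
        assert em.pair(0, "A", "r1", 1, "B", "r1") == 2.5
        assert em.pair(1, "B", "r1", 0, "A", "r1") == 2.5
        assert len(em.pairs) == 1

    def test_rt_default_is_physiological(self):
        assert Constants().RT == pytest.approx(0.5925, abs=5e-4)


class TestEnergiesAndCounting:
    @pytest.mark.parametrize(
        "conf, expected",
        [
            ((("X", "x1"), ("Z", "z1")), 0.0),
            ((("X", "x2"), ("Z", "z1")), 2.0),  # 1 single + 1 pair
            ((("X", "x2"), ("Z", "z2")), 3.0),
            ((("Y", "y1"), ("Z", "z2")), 7.0),
        ],
    )
    def test_lower_bound_energy_matches_matrix_sums(self, toy1, conf, expected):
        assert lower_bound_energy(toy1, conf) == pytest.approx(expected)

    def test_partial_conformation_rejected(self, toy1):
        with pytest.raises(ValidationError):
            lower_bound_energy(toy1, ((("X", "x1"),)))

    def test_conf_count_toy(self, toy1):
        assert conf_count(toy1, X) == 4
        assert conf_count(toy1, Y) == 2

    @pytest.mark.parametrize("seed", range(5))
    def test_conf_count_equals_enumeration(self, seed):
        problem = small_problem(seed)
        for role in ("protein", "ligand", "complex"):
            state = problem.states[role]
            for seq in all_state_sequences(state):
                assert conf_count(state, seq) == len(
                    brute_conformations(state, seq)
                )

    def test_conf_count_is_arbitrary_precision(self):
        # 40 positions x 2 rotamers: ~1.1e12 conformations, exact integer
        types = (ResidueType("W", ("r0", "r1")),)
        em = EnergyMatrix()
        for i in range(40):
            for r in ("r0", "r1"):
                em.set_single(i, "W", r, 0.0)
        from kstardesign.confspace import State

        state = State(
            role="complex",
            positions=[
                DesignPosition(i, f"p{i}", types, "W") for i in range(40)
            ],
            ematrix=em,
        )
        assert conf_count(state, Sequence()) == 2**40


class TestMinimizedEnergyModel:
    def test_identity_returns_lower_bound(self):
        m = MinimizedEnergyModel(kind="identity")
        assert m.energy("complex", (("X", "x1"),), -3.25) == -3.25

    @pytest.mark.parametrize("seed", range(3))
    def test_seeded_offset_bounded_and_deterministic(self, seed):
        problem = generate_problem(GeneratorParams(seed=seed, delta_max=0.3,
                                                   n_protein_pos=2, n_ligand_pos=2,
                                                   types_per_mutable=2,
                                                   rotamers_max=3))
        state = problem.complex
        for seq in all_state_sequences(state)[:2]:
            for conf, lb in brute_conformations(state, seq):
                e1 = state.minimizer.energy(state.role, conf, lb)
                e2 = state.minimizer.energy(state.role, conf, lb)
                assert e1 == e2
                assert lb <= e1 <= lb + 0.3

    @pytest.mark.parametrize("seed", range(4))
    def test_minimized_never_below_lower_bound_exhaustive(self, seed):
        problem = small_problem(seed)
        for role in ("protein", "ligand", "complex"):
            state = problem.states[role]
            for seq in all_state_sequences(state):
                for conf, lb in brute_conformations(state, seq):
                    assert state.minimizer.energy(state.role, conf, lb) >= lb


class TestProjection:
    def test_projections_toy(self, toy2):
        y = Sequence.from_dict({0: "Y"})
        assert project_sequence(toy2, y, "protein") == Sequence.from_dict({0: "Y"})
        assert project_sequence(toy2, y, "ligand") == Sequence()
        assert project_sequence(toy2, y, "complex") == y

    def test_unmapped_position_rejected(self, toy2):
        bad = Sequence.from_dict({7: "X"})
        with pytest.raises(ValidationError):
            project_sequence(toy2, bad, "protein")


class TestSchemaIO:
    def test_round_trip_preserves_everything(self, toy2):
        text = dumps_problem(toy2)
        again = dumps_problem(loads_problem(text))
        assert text == again

    @pytest.mark.parametrize("seed", [1, 11])
    def test_round_trip_synthetic_full_precision(self, seed):
        problem = small_problem(seed)
        loaded = loads_problem(dumps_problem(problem))
        for role in ("protein", "ligand", "complex"):
            assert loaded.states[role].ematrix.singles == \
                problem.states[role].ematrix.singles
            assert loaded.states[role].ematrix.pairs == \
                problem.states[role].ematrix.pairs

    def test_missing_singles_entry_is_validation_error(self, toy2):
        obj = json.loads(dumps_problem(toy2))
        obj["states"]["protein"]["ematrix"]["singles"].pop()
        with pytest.raises(ValidationError, match="missing singles"):
            loads_problem(json.dumps(obj))

    def test_missing_state_is_schema_error(self, toy2):
        obj = json.loads(dumps_problem(toy2))
        del obj["states"]["ligand"]
        with pytest.raises(SchemaError):
            loads_problem(json.dumps(obj))

    def test_bad_wild_type_is_validation_error(self, toy2):
        obj = json.loads(dumps_problem(toy2))
        obj["wild_type"] = {"0": "NOPE"}
        with pytest.raises(ValidationError):
            loads_problem(json.dumps(obj))

    def test_mutable_complex_position_must_map_to_mutable_partner(self, toy2):
        obj = json.loads(dumps_problem(toy2))
        # make complex p1 mutable without making the ligand position mutable
        obj["states"]["complex"]["positions"][1]["types"].append(
            {"name": "Q", "rotamers": ["q1"]}
        )
        obj["states"]["complex"]["positions"][1]["mutable"] = True
        obj["states"]["complex"]["ematrix"]["singles"].append([1, "Q", "q1", 0.0])
        obj["wild_type"] = {"0": "X", "1": "Z"}
        with pytest.raises(ValidationError, match="immutable"):
            loads_problem(json.dumps(obj))
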