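"""Partition-function estimators: exact values, provable bounds, halting."""

import math

import pytest

from kstardesign.confspace import Sequence
from kstardesign.partition import (
    GuardLimitError,
    approx_partition_eps,
    ewakstar_partition,
    exact_partition,
)
from kstardesign.synthgen import GeneratorParams, generate_problem

from _brute import (
    all_state_sequences,
    brute_gmec_energy,
    brute_log_z,
    brute_minimized,
)
from conftest import small_problem

X = Sequence.from_dict({0: "X"})
Y = Sequence.from_dict({0: "Y"})

Z_X = 1.0 + 2 * math.exp(-2.0) + math.exp(-3.0)  # 1.3204577
Z_Y = math.exp(-5.0) + math.exp(-7.0)  # 0.0076498


class TestExact:
    def test_toy_values(self, toy1):
        rx = exact_partition(toy1, X, rt=1.0)
        assert math.exp(rx.log_z_lower) == pytest.approx(Z_X, rel=1e-12)
        assert rx.log_z_lower == rx.log_z_upper
        assert rx.halting_reason == "exhausted"
        assert rx.n_minimized == 4
        ry = exact_partition(toy1, Y, rt=1.0)
        assert math.exp(ry.log_z_lower) == pytest.approx(Z_Y, rel=1e-12)

    def test_all_zero_matrix_gives_conformation_count(self):
        problem = generate_problem(
            GeneratorParams(sigma_single=0.0, sigma_pair=0.0, p_clash=0.0,
                            delta_max=0.0, n_protein_pos=2, n_ligand_pos=2,
                            types_per_mutable=2, rotamers_min=2,
                            rotamers_max=3, seed=0)
        )
        state = problem.complex
        seq = problem.wild_type_sequence
        from kstardesign.confspace import conf_count

        res = exact_partition(state, seq, rt=1.0)
        assert math.exp(res.log_z_lower) == pytest.approx(conf_count(state, seq))

    def test_guard_limit_refusal(self, toy1):
        with pytest.raises(GuardLimitError):
            exact_partition(toy1, X, rt=1.0, guard_limit=3)


class TestEpsilon:
    def test_toy_hand_trace(self, toy1):
        res = approx_partition_eps(toy1, X, epsilon=0.3, rt=1.0)
        assert res.n_minimized == 1
        assert math.exp(res.log_z_lower) == pytest.approx(1.0)
        assert math.exp(res.log_z_upper) == pytest.approx(1.0 + 3 * math.exp(-2.0))
        assert res.halting_reason == "epsilon_met"
        assert math.exp(res.log_z_lower) >= (1 - 0.3) * Z_X

    def test_epsilon_zero_exhausts(self, toy1):
        res = approx_partition_eps(toy1, X, epsilon=0.0, rt=1.0)
        assert res.halting_reason == "exhausted"
        assert math.exp(res.log_z_lower) == pytest.approx(Z_X, rel=1e-12)

    def test_epsilon_out_of_range(self, toy1):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                approx_partition_eps(toy1, X, epsilon=bad, rt=1.0)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("eps", [0.1, 0.32, 0.68])
    def test_contract_on_synthetic(self, seed, eps):
        problem = small_problem(seed)
        state = problem.complex
        rt = problem.constants.RT
        for seq in all_state_sequences(state):
            log_z = brute_log_z(state, seq, rt)
            res = approx_partition_eps(state, seq, epsilon=eps, rt=rt)
            assert res.log_z_lower >= math.log(1 - eps) + log_z - 1e-9
            assert res.log_z_lower <= log_z + 1e-9 <= res.log_z_upper + 2e-9


class TestWindow:
    def test_toy_hand_trace(self, toy1):
        res = ewakstar_partition(toy1, X, w_conf=2.5, rt=1.0, keep_ensemble=True)
        assert res.n_minimized == 3  # energies 0, 2, 2; halts at lb 3
        assert math.exp(res.log_z_lower) == pytest.approx(1 + 2 * math.exp(-2.0))
        assert math.exp(res.log_z_upper) == pytest.approx(Z_X)
        assert res.halting_reason == "window_exceeded"
        assert {e for _, e in res.ensemble} == {0.0, 2.0}

    def test_large_window_exhausts(self, toy1):
        res = ewakstar_partition(toy1, X, w_conf=100.0, rt=1.0)
        assert res.halting_reason == "exhausted"
        assert math.exp(res.log_z_lower) == pytest.approx(Z_X, rel=1e-12)

    def test_negative_window_rejected(self, toy1):
        with pytest.raises(ValueError):
            ewakstar_partition(toy1, X, w_conf=-1.0, rt=1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_ensemble_superset_guarantee(self, seed):
        problem = small_problem(seed)
        state = problem.complex
        rt = problem.constants.RT
        for seq in all_state_sequences(state):
            gmec = brute_gmec_energy(state, seq)
            within = {
                conf for conf, e in brute_minimized(state, seq)
                if e <= gmec + 1.0
            }
            res = ewakstar_partition(state, seq, w_conf=1.0, rt=rt,
                                     keep_ensemble=True)
            retained = {conf for conf, _ in res.ensemble}
            assert within <= retained

    @pytest.mark.parametrize("seed", [2, 9])
    def test_lower_bound_monotone_in_window(self, seed):
        problem = small_problem(seed)
        state = problem.complex
        rt = problem.constants.RT
        for seq in all_state_sequences(state)[:4]:
            log_z = brute_log_z(state, seq, rt)
            prev = -math.inf
            for w in (0.0, 0.5, 1.0, 2.0, 5.0, 50.0):
                res = ewakstar_partition(state, seq, w_conf=w, rt=rt)
                assert res.log_z_lower >= prev - 1e-12
                assert res.log_z_lower <= log_z + 1e-9 <= res.log_z_upper + 2e-9
                prev = res.log_z_lower
            assert prev == pytest.approx(log_z, abs=1e-9)  # w=50 exhausts


class TestNumericalRange:
    def test_no_underflow_across_hundreds_of_orders(self, toy1):
        # RT tiny -> ln Z around -5000: must stay finite in the log domain
        res = exact_partition(toy1, Y, rt=1e-3)
        assert math.isfinite(res.log_z_lower)
        assert res.log_z_lower == pytest.approx(-5000.0, rel=1e-6)
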